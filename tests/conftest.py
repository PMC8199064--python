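import numpy as np
import pytest

import hsibrain as hb


@pytest.fixture(scope="session")
def library():
    return hb.make_signature_library(seed=1, separation=0.08)


@pytest.fixture(scope="session")
def xtalk():
    return hb.make_crosstalk_model()


@pytest.fixture(scope="session")
def ideal_scene(library):
    """Noise-free scene with illumination variation (exact forward model)."""
    return hb.make_phantom_scene(library, 20, 24, noise_sd=0.0,
                                 illum_amplitude=0.5, seed=3)


@pytest.fixture(scope="session")
def ideal_capture(ideal_scene, xtalk):
    return hb.render_capture(ideal_scene, xtalk)


@pytest.fixture(scope="session")
def ideal_norm_cube(ideal_capture, xtalk):
    raw, white, dark = ideal_capture
    cube, coef = hb.preprocess_capture(raw, white, dark, xtalk.scm)
    return cube


@pytest.fixture(scope="session")
def separable_images():
    """Small well-separated phantom cohort through the full chain."""
    images, _ = hb.simulate_preprocessed_suite(
        separation=0.3, n_scenes=3, rows=32, cols=32, seed=21)
    return images


@pytest.fixture(scope="session")
def small_spectra_dataset(separable_images):
    """Pooled per-pixel spectra dataset of the separable cohort."""
    spec = hb.ModelSpec("svm-linear", seed=0)
    return hb.LabeledDataset.concat(
        [hb.build_dataset(c, g, spec, image_id=i)
         for i, (c, g) in enumerate(separable_images)])
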