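"""Synthetic snapshot-mosaic scenes with known ground truth.

The in-vivo captures this pipeline was designed for are not distributable,
so every downstream stage is exercised on phantoms: smooth 25-band tissue
signatures for the five annotated classes, blobby class regions, a smooth
multiplicative illumination field (the brain surface is curved, so pixels
sit at different heights and collect different light), sensor noise, a
diagonally dominant crosstalk mixing matrix, and the 5x5 mosaic sampling of
the snapshot sensor.

The qualitative relations of the real cohort are built in: healthy tissue
and tumor are nearly parallel spectra separated by a tunable perturbation,
venous and arterial blood resemble each other more than anything else, and
dura mater is the most distinct class.  Class-abundance defaults mirror the
strong imbalance of the real annotations (arterial blood rare, healthy and
tumor abundant).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .classes import ARTERIAL, CLASS_IDS, DURA, HEALTHY, TUMOR, UNLABELED, VENOUS
from .preprocess import (
    N_BANDS,
    HyperCube,
    RawMosaicFrame,
    SpectralCorrectionMatrix,
    remosaic,
)

#: default labeled-pixel fractions of the whole image, modeled on the
#: imbalance of the real cohort's annotations (healthy ~45%, tumor ~24%,
#: venous ~5%, arterial ~2%, dura ~24% of labeled pixels; ~84% labeled).
DEFAULT_CLASS_FRACTIONS = {
    HEALTHY: 0.38,
    TUMOR: 0.20,
    VENOUS: 0.045,
    ARTERIAL: 0.017,
    DURA: 0.20,
}

#: spectrum assigned to unlabeled background pixels: a strongly sloped ramp
#: so the surround is angularly distinct from every tissue class (dura in
#: particular is nearly flat; a flat gray surround would alias with it
#: under spectral-angle labeling)
_BACKGROUND_SIGNATURE = 0.15 + 0.3 * np.linspace(0.0, 1.0, N_BANDS)

DEFAULT_SEPARATION = 0.08
DEFAULT_NOISE_SD = 0.01
DEFAULT_ILLUM_AMPLITUDE = 0.6
DEFAULT_WHITE_LEVEL = 0.9
DEFAULT_DARK_LEVEL = 0.05


# ---------------------------------------------------------------------------
# signature library
# ---------------------------------------------------------------------------

@dataclass
class SignatureLibrary:
    """Per-class mean 25-band reflectance signatures and within-class spread.

    ``separation`` controls how far the tumor signature diverges from the
    healthy one (0 means identical); the divergence direction is orthogonal
    to the healthy spectrum so the spectral angle between them grows
    strictly with ``separation``.
    """

    signatures: dict[int, np.ndarray]
    within_sd: dict[int, np.ndarray]
    separation: float
    seed: int

    def signature(self, class_id: int) -> np.ndarray:
        return self.signatures[class_id]


def _smooth_unit(rng: np.random.Generator, sigma: float = 2.0) -> np.ndarray:
    """Smooth random 25-vector scaled to unit max-abs."""
    v = gaussian_filter1d(rng.standard_normal(N_BANDS), sigma, mode="nearest")
    return v / np.max(np.abs(v))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def make_signature_library(
    seed: int,
    separation: float = DEFAULT_SEPARATION,
    jitter: float = 0.01,
) -> SignatureLibrary:
    """Build the five-class signature library, deterministic in ``seed``.

    Mean spectra are smooth parametric curves over the 655-975 nm range
    (25 bands) plus a small seeded smooth perturbation per class:

    * healthy: moderate reflectance rising gently into the NIR;
    * tumor:   ``healthy + separation * u`` with ``u`` a smooth unit
      max-abs shape orthogonalized against the healthy spectrum;
    * venous:  dark in the red, rising steeply (deoxygenated blood);
    * arterial: same family as venous, slightly brighter and shifted;
    * dura:    bright and nearly flat, the most distinct signature.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, N_BANDS)

    healthy = 0.35 + 0.15 * _sigmoid((t - 0.30) / 0.15)
    venous = 0.10 + 0.26 * _sigmoid((t - 0.50) / 0.10)
    arterial = 0.16 + 0.26 * _sigmoid((t - 0.42) / 0.10)
    dura = 0.66 - 0.06 * t + 0.02 * np.sin(2.5 * t)

    sigs = {HEALTHY: healthy, VENOUS: venous, ARTERIAL: arterial, DURA: dura}
    for cid in sigs:
        sigs[cid] = sigs[cid] + jitter * _smooth_unit(rng)

    # tumor divergence: smooth shape, orthogonal to healthy so the spectral
    # angle grows monotonically with the separation parameter
    u = _smooth_unit(rng)
    h = sigs[HEALTHY]
    u = u - (u @ h) / (h @ h) * h
    u = u / np.max(np.abs(u))
    sigs[TUMOR] = h + separation * u

    for cid in CLASS_IDS:
        sigs[cid] = np.clip(sigs[cid], 0.02, 0.98)

    within = {
        HEALTHY: np.full(N_BANDS, 0.010),
        TUMOR: np.full(N_BANDS, 0.010),
        VENOUS: np.full(N_BANDS, 0.020),
        ARTERIAL: np.full(N_BANDS, 0.020),
        DURA: np.full(N_BANDS, 0.025),
    }
    return SignatureLibrary(signatures=sigs, within_sd=within,
                            separation=float(separation), seed=int(seed))


def perturb_library(
    library: SignatureLibrary,
    amount: float,
    seed: int,
    classes: Optional[Sequence[int]] = None,
) -> SignatureLibrary:
    """Return a copy with smooth per-class signature shifts of max-abs ``amount``.

    Used to emulate inter-patient spectral variability: each scene of a
    phantom cohort gets its own slightly shifted library.
    """
    rng = np.random.default_rng(seed)
    classes = tuple(classes) if classes is not None else CLASS_IDS
    sigs = {}
    for cid in CLASS_IDS:
        s = library.signatures[cid].copy()
        if cid in classes and amount > 0:
            s = np.clip(s + amount * _smooth_unit(rng), 0.02, 0.98)
        sigs[cid] = s
    return SignatureLibrary(signatures=sigs,
                            within_sd={k: v.copy() for k, v in library.within_sd.items()},
                            separation=library.separation, seed=library.seed)


# ---------------------------------------------------------------------------
# crosstalk
# ---------------------------------------------------------------------------

@dataclass
class CrosstalkModel:
    """Diagonally dominant 25x25 band-mixing matrix and its exported inverse.

    The mixing matrix is symmetric and doubly stochastic (Sinkhorn-balanced
    exponential-decay kernel), so rows and columns both sum to 1, the white
    and dark reference frames stay spectrally flat, and the exported
    spectral correction matrix is a true inverse in the row-vector
    convention used by the pre-processing chain.
    """

    mixing: np.ndarray
    correction: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.mixing = np.asarray(self.mixing, dtype=np.float64)
        if self.mixing.shape != (N_BANDS, N_BANDS):
            raise ValueError("mixing matrix must be 25x25")
        self.correction = np.linalg.inv(self.mixing)

    @property
    def scm(self) -> SpectralCorrectionMatrix:
        """The correction matrix packaged for the pre-processing chain."""
        return SpectralCorrectionMatrix(self.correction.copy())


def make_crosstalk_model(leak: float = 0.08, decay: float = 1.2) -> CrosstalkModel:
    """Nearest-neighbor band leakage with exponentially decaying off-diagonals.

    ``leak`` is the relative weight of the first neighbor; dominance
    requires the total off-diagonal mass per row to stay below the diagonal
    (guaranteed for ``leak`` < ~0.2 at the default decay).
    """
    if leak < 0:
        raise ValueError("leak must be >= 0")
    idx = np.arange(N_BANDS)
    dist = np.abs(idx[:, None] - idx[None, :]).astype(float)
    a = np.where(dist == 0, 1.0, leak * np.exp(-(dist - 1.0) / decay))
    # symmetric Sinkhorn balancing: M = diag(d) A diag(d) with unit row sums
    d = np.ones(N_BANDS)
    for _ in range(500):
        rs = (a * d[None, :]).sum(axis=1) * d
        d = d / np.sqrt(rs)
        if np.max(np.abs((a * d[None, :] * d[:, None]).sum(axis=1) - 1.0)) < 1e-14:
            break
    m = a * d[None, :] * d[:, None]
    return CrosstalkModel(mixing=m)


# ---------------------------------------------------------------------------
# phantom scenes
# ---------------------------------------------------------------------------

@dataclass
class PhantomScene:
    """A synthetic brain-surface scene with known per-pixel ground truth.

    ``cube`` holds the true reflectance: class signature scaled by the local
    illumination value plus zero-mean noise, clipped to be nonnegative.
    """

    region_map: np.ndarray        # rows x cols int, 0 unlabeled, 1-5 classes
    cube: np.ndarray              # rows x cols x 25 true reflectance
    illumination: np.ndarray      # rows x cols strictly positive
    noise_sd: float
    seed: int
    library: SignatureLibrary


def _illumination_field(
    rows: int, cols: int, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Low-order polynomial dome, amplitude = max/min - 1, strictly positive."""
    r0 = rows * (0.35 + 0.3 * rng.random())
    c0 = cols * (0.35 + 0.3 * rng.random())
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    d2 = ((rr - r0) / rows) ** 2 + ((cc - c0) / cols) ** 2
    g = 1.0 - d2 / max(d2.max(), 1e-12)  # in [0, 1], 1 at the dome apex
    return 1.0 + amplitude * g


def make_phantom_scene(
    library: SignatureLibrary,
    rows: int,
    cols: int,
    class_fractions: Optional[dict[int, float]] = None,
    illum_amplitude: float = DEFAULT_ILLUM_AMPLITUDE,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    smooth: Optional[float] = None,
) -> PhantomScene:
    """Generate a phantom scene with blobby class regions.

    Regions are thresholded smoothed random fields, one per class, assigned
    in class-id order (lowest id wins on overlap) with pixel counts matching
    the requested fractions exactly.  Labeled pixel spectra are the class
    signature (plus within-class spectral jitter) scaled by the local
    illumination and perturbed by sensor noise.

    ``noise_sd = 0`` requests an idealized scene: both sensor noise and
    within-class jitter are disabled, so every labeled pixel's spectrum is
    exactly its class mean times the illumination value.
    """
    fractions = dict(DEFAULT_CLASS_FRACTIONS if class_fractions is None
                     else class_fractions)
    if any(f < 0 for f in fractions.values()):
        raise ValueError("class fractions must be nonnegative")
    if sum(fractions.values()) > 1.0 + 1e-9:
        raise ValueError("class fractions must sum to at most 1")
    rng = np.random.default_rng(seed)
    n_pix = rows * cols
    sigma = smooth if smooth is not None else max(2.0, min(rows, cols) / 8.0)

    region = np.zeros(n_pix, dtype=np.int8)
    for cid in CLASS_IDS:
        n_c = int(round(fractions.get(cid, 0.0) * n_pix))
        if n_c == 0:
            continue
        fld = gaussian_filter(rng.standard_normal((rows, cols)), sigma,
                              mode="nearest").ravel()
        avail = np.flatnonzero(region == 0)
        take = avail[np.argsort(fld[avail])[::-1][:n_c]]
        region[take] = cid
    region = region.reshape(rows, cols)

    illum = (_illumination_field(rows, cols, illum_amplitude, rng)
             if illum_amplitude > 0 else np.ones((rows, cols)))

    cube = np.empty((rows, cols, N_BANDS))
    cube[:] = _BACKGROUND_SIGNATURE[None, None, :] * illum[:, :, None]
    for cid in CLASS_IDS:
        mask = region == cid
        n_c = int(mask.sum())
        if n_c == 0:
            continue
        spectra = np.tile(library.signatures[cid], (n_c, 1))
        if noise_sd > 0:
            spectra = spectra + rng.standard_normal((n_c, N_BANDS)) * \
                library.within_sd[cid][None, :]
        cube[mask] = spectra * illum[mask][:, None]
    if noise_sd > 0:
        cube += rng.standard_normal(cube.shape) * noise_sd
    np.clip(cube, 0.0, None, out=cube)

    return PhantomScene(region_map=region, cube=cube, illumination=illum,
                        noise_sd=float(noise_sd), seed=int(seed), library=library)


def make_phantom_suite(
    library: SignatureLibrary,
    n_scenes: int,
    rows: int,
    cols: int,
    seed: int = 0,
    inter_scene_sd: float = 0.0,
    **scene_kwargs,
) -> list[PhantomScene]:
    """A cohort of phantom scenes, optionally with inter-scene signature shifts.

    ``inter_scene_sd`` > 0 gives every scene its own smoothly perturbed
    signature library, emulating inter-patient spectral variability.
    """
    scenes = []
    for i in range(n_scenes):
        lib_i = (perturb_library(library, inter_scene_sd, seed=seed + 1000 + i)
                 if inter_scene_sd > 0 else library)
        scenes.append(make_phantom_scene(lib_i, rows, cols,
                                         seed=seed + 10 * i, **scene_kwargs))
    return scenes


def simulate_preprocessed_suite(
    separation: float = DEFAULT_SEPARATION,
    n_scenes: int = 4,
    rows: int = 40,
    cols: int = 40,
    seed: int = 0,
    inter_scene_sd: float = 0.0,
    noise_sd: float = DEFAULT_NOISE_SD,
    crosstalk: Optional[CrosstalkModel] = None,
    **scene_kwargs,
):
    """Phantom cohort rendered through the full sensor + pre-processing chain.

    Returns ``(images, scenes)`` where ``images`` is a list of
    ``(normalized HyperCube, GroundTruthMap)`` pairs ready for the
    experiment runners — the ground truth is the generator's own region
    map, so every downstream claim can be checked against it.
    """
    from .labeling import GroundTruthMap
    from .preprocess import preprocess_capture

    lib = make_signature_library(seed=seed, separation=separation)
    xtalk = crosstalk if crosstalk is not None else make_crosstalk_model()
    scenes = make_phantom_suite(lib, n_scenes, rows, cols, seed=seed,
                                inter_scene_sd=inter_scene_sd,
                                noise_sd=noise_sd, **scene_kwargs)
    images = []
    for sc in scenes:
        raw, white, dark = render_capture(sc, xtalk)
        cube, _ = preprocess_capture(raw, white, dark, xtalk.scm)
        images.append((cube, GroundTruthMap(sc.region_map)))
    return images, scenes


# ---------------------------------------------------------------------------
# forward sensor model
# ---------------------------------------------------------------------------

def render_capture(
    scene: PhantomScene,
    crosstalk: CrosstalkModel,
    white_level: float = DEFAULT_WHITE_LEVEL,
    dark_level: float = DEFAULT_DARK_LEVEL,
) -> tuple[RawMosaicFrame, RawMosaicFrame, RawMosaicFrame]:
    """Forward-simulate the raw mosaic capture plus white/dark references.

    Per pixel: radiance = reflectance * (white - dark) + dark, the 25-band
    radiance vector is mixed by the crosstalk matrix, and the mixed bands
    are laid out in 5x5 mosaic blocks (raw dims = 5*rows x 5*cols).  The
    white frame is rendered from unit reflectance and the dark frame from
    zero reflectance through the same model, which is exactly what the
    calibration and spectral-correction steps invert.
    """
    if white_level <= dark_level or dark_level < 0:
        raise ValueError("require white_level > dark_level >= 0")

    def _render(reflectance: np.ndarray) -> RawMosaicFrame:
        radiance = reflectance * (white_level - dark_level) + dark_level
        mixed = radiance @ crosstalk.mixing
        return remosaic(HyperCube(mixed))

    rows, cols = scene.region_map.shape
    raw = _render(scene.cube)
    white = _render(np.ones((rows, cols, N_BANDS)))
    dark = _render(np.zeros((rows, cols, N_BANDS)))
    return raw, white, dark
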