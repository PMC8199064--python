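"""Stratified folds, nested CV bookkeeping, experiment runner contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hsibrain as hb


class TestStratifiedKfold:
    def test_exact_division(self):
        labels = np.ones(100)
        fa = hb.stratified_kfold(labels, 5, seed=0)
        assert all((fa.fold == f).sum() == 20 for f in range(1, 6))

    def test_round_robin_remainder_multiset(self):
        fa = hb.stratified_kfold(np.ones(7), 5, seed=1)
        sizes = sorted(((fa.fold == f).sum() for f in range(1, 6)),
                       reverse=True)
        assert sizes == [2, 2, 1, 1, 1]

    def test_deterministic_in_seed(self):
        labels = np.random.default_rng(0).integers(1, 6, 200)
        a = hb.stratified_kfold(labels, 5, seed=9)
        b = hb.stratified_kfold(labels, 5, seed=9)
        np.testing.assert_array_equal(a.fold, b.fold)

    def test_small_class_rejected_by_name(self):
        labels = np.r_[np.ones(50), np.full(3, 4.0)]
        with pytest.raises(ValueError, match="class 4"):
            hb.stratified_kfold(labels, 5, seed=0)

    @settings(max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_per_class_fold_counts_within_one(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.concatenate([
            np.full(rng.integers(5, 40), cid) for cid in range(1, 6)])
        fa = hb.stratified_kfold(labels, 5, seed=seed)
        assert np.isin(fa.fold, [1, 2, 3, 4, 5]).all()
        for cid in range(1, 6):
            counts = [((labels == cid) & (fa.fold == f)).sum()
                      for f in range(1, 6)]
            assert max(counts) - min(counts) <= 1

    def test_partition_property(self):
        labels = np.random.default_rng(1).integers(1, 6, 120)
        fa = hb.stratified_kfold(labels, 5, seed=2)
        seen = np.concatenate([fa.test_indices(f) for f in range(1, 6)])
        assert sorted(seen) == list(range(120))


@pytest.fixture(scope="module")
def report(small_spectra_dataset):
    return hb.double_cv(small_spectra_dataset,
                        hb.ModelSpec("svm-linear", seed=4), seed=5)


@pytest.fixture(scope="module")
def result(separable_images):
    return hb.run_experiment_a(separable_images,
                               hb.ModelSpec("svm-linear", seed=1), seed=2)


class TestDoubleCV:
    def test_trains_exactly_25_models(self, report):
        assert report.models_trained == 25

    def test_every_sample_in_exactly_one_outer_test_fold(
            self, report, small_spectra_dataset):
        n = len(small_spectra_dataset)
        seen = np.concatenate([r["test_idx"] for r in report.per_outer])
        assert sorted(seen.tolist()) == list(range(n))

    def test_outer_test_fold_isolated_from_inner_loop(self, report):
        for r in report.per_outer:
            # the inner loop only ever sees the outer-training samples
            assert r["inner_folds"].fold.shape[0] == r["train_idx"].shape[0]
            assert np.intersect1d(r["train_idx"], r["test_idx"]).size == 0

    def test_winner_has_best_outer_test_oacc(self, report):
        best = max(r["test_oacc"] for r in report.per_outer)
        assert report.winner_test_oacc == best

    def test_separable_cohort_reaches_perfect_test_oacc(self, report):
        assert report.winner_test_oacc == 1.0

    def test_winner_model_never_saw_its_outer_test_samples(
            self, report, small_spectra_dataset):
        # fingerprints identify the calibration subset the winner was fit on
        win = report.per_outer[report.winner_outer - 1]
        sub = small_spectra_dataset.subset(win["train_idx"])
        calib = sub.subset(win["inner_folds"].train_indices(
            win["inner_selected"]))
        assert report.winner_model.fingerprint == calib.fingerprint()


class TestExperimentA:
    def test_trains_five_double_cvs(self, result):
        assert result.models_trained == 5 * 25

    def test_evaluates_exactly_five_fold_groupings(self, result):
        assert [g["grouping"] for g in result.detail["groupings"]] == \
            [1, 2, 3, 4, 5]

    def test_training_fraction_is_80_percent_per_image(self, separable_images):
        spec = hb.ModelSpec("svm-linear", seed=1)
        ds = hb.build_dataset(*separable_images[0], spec, image_id=0)
        fa = hb.stratified_kfold(ds.y, 5, seed=0)
        for cid in np.unique(ds.y):
            n_cls = (ds.y == cid).sum()
            for g in range(1, 6):
                n_train = ((ds.y == cid) & (fa.fold != g)).sum()
                assert abs(n_train - 0.8 * n_cls) <= 1

    def test_separable_suite_classified_almost_perfectly(self, result):
        for res in result.images:
            assert res.test_fold_report.oacc >= 0.95
            assert res.full_image_report.oacc >= 0.95

    def test_maps_cover_images(self, result, separable_images):
        for res, (cube, _) in zip(result.images, separable_images):
            assert res.classification_map.labels.shape == cube.spatial_shape

    def test_fewer_than_two_images_rejected(self, separable_images):
        with pytest.raises(ValueError):
            hb.run_experiment_a(separable_images[:1],
                                hb.ModelSpec("svm-linear"), seed=0)


class TestExperimentB:
    def test_leave_one_out_contract_and_model_count(self, separable_images):
        res = hb.run_experiment_b(separable_images,
                                  hb.ModelSpec("svm-linear", seed=1), seed=3,
                                  predict_full_images=False)
        n = len(separable_images)
        assert res.models_trained == n * 25
        assert len(res.detail["selected_models"]) == n
        # each selected model was fit on a pool excluding its test image
        for i, model in enumerate(res.detail["selected_models"]):
            test_ds = hb.spectra_dataset(*separable_images[i], image_id=i)
            assert model.fingerprint != test_ds.fingerprint()

    def test_identical_cohorts_make_experiments_agree(self, library, xtalk):
        # same phantom repeated: inter-patient CV matches intra-patient CV
        lib = hb.make_signature_library(seed=31, separation=0.25)
        scene = hb.make_phantom_scene(lib, 32, 32, seed=17, noise_sd=0.01)
        raw, white, dark = hb.render_capture(scene, xtalk)
        cube, _ = hb.preprocess_capture(raw, white, dark, xtalk.scm)
        images = [(cube, hb.GroundTruthMap(scene.region_map))] * 3
        spec = hb.ModelSpec("svm-linear", seed=2)
        res_a = hb.run_experiment_a(images, spec, seed=4,
                                    predict_full_images=False)
        res_b = hb.run_experiment_b(images, spec, seed=4,
                                    predict_full_images=False)
        oacc_a = np.mean([r.test_fold_report.oacc for r in res_a.images])
        oacc_b = np.mean([r.full_image_report.oacc for r in res_b.images])
        assert abs(oacc_a - oacc_b) <= 0.02

    def test_shifted_tumor_signature_lowers_that_scenes_sensitivity(
            self, xtalk):
        lib = hb.make_signature_library(seed=51, separation=0.12)
        scenes = [hb.make_phantom_scene(lib, 32, 32, seed=60 + i,
                                        noise_sd=0.01) for i in range(3)]
        # one scene's tumor signature is shifted toward healthy tissue
        # (same seed: identical curves except the collapsed separation)
        shifted_lib = hb.make_signature_library(seed=51, separation=0.02)
        scenes.append(hb.make_phantom_scene(shifted_lib, 32, 32, seed=63,
                                            noise_sd=0.01))
        images = []
        for sc in scenes:
            raw, white, dark = hb.render_capture(sc, xtalk)
            cube, _ = hb.preprocess_capture(raw, white, dark, xtalk.scm)
            images.append((cube, hb.GroundTruthMap(sc.region_map)))
        res = hb.run_experiment_b(images, hb.ModelSpec("svm-linear", seed=1),
                                  seed=5, predict_full_images=False)
        sens = [r.full_image_report.per_class[hb.TUMOR]["SEN"]
                for r in res.images]
        assert sens[3] < min(sens[:3])
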