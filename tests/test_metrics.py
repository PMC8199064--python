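"""Metric suite vs independent brute-force tallies and printed arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hsibrain as hb


def brute_force_counts(y_true, y_pred, k):
    """Independent tally oracle: plain Python pair counting."""
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == k and p == k)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == k and p != k)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t != k and p == k)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t != k and p != k)
    return tp, tn, fp, fn


@pytest.fixture(scope="module")
def random_pairs():
    rng = np.random.default_rng(11)
    return rng.integers(1, 6, 1000), rng.integers(1, 6, 1000)


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        y = np.array([1, 2, 3, 4, 5, 5])
        cm = hb.confusion(y, y)
        assert (cm == np.diag(np.diag(cm))).all()
        assert cm.sum() == 6

    def test_single_off_diagonal_sample(self):
        cm = hb.confusion([2], [3])
        assert cm[1, 2] == 1 and cm.sum() == 1

    def test_matches_brute_force_pair_counting(self, random_pairs):
        y_true, y_pred = random_pairs
        cm = hb.confusion(y_true, y_pred)
        for i in range(1, 6):
            for j in range(1, 6):
                expected = sum(1 for t, p in zip(y_true, y_pred)
                               if t == i and p == j)
                assert cm[i - 1, j - 1] == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hb.confusion([1, 2], [1])


class TestOacc:
    def test_diagonal_matrix_scores_one(self):
        assert hb.oacc(np.diag([3, 1, 4, 1, 5])) == 1.0

    def test_zero_diagonal_scores_zero(self):
        cm = np.ones((5, 5), dtype=int) - np.eye(5, dtype=int)
        assert hb.oacc(cm) == 0.0

    def test_two_class_example(self):
        cm = np.zeros((5, 5), dtype=int)
        cm[0, 0], cm[0, 1], cm[1, 0], cm[1, 1] = 40, 10, 20, 30
        assert hb.oacc(cm) == pytest.approx(0.70)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            hb.oacc(np.zeros((5, 5), dtype=int))

    def test_equals_count_weighted_mean_of_sensitivities(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            cm = rng.integers(0, 30, (5, 5))
            row = cm.sum(axis=1)
            sens = np.array([np.nan if row[k] == 0 else cm[k, k] / row[k]
                             for k in range(5)])
            valid = row > 0
            expected = (sens[valid] * row[valid]).sum() / row.sum()
            assert hb.oacc(cm) == pytest.approx(expected)


class TestClassMetrics:
    def test_perfect_prediction_metrics(self):
        cm = np.diag([3, 1, 4, 1, 5])
        for cid in hb.CLASS_IDS:
            m = hb.class_metrics(cm, cid)
            assert m["ACC"] == 1 and m["SEN"] == 1 and m["SPE"] == 1
            assert m["Error"] == 0

    def test_hand_computed_example(self):
        # class 1: TP=3, FN=1, FP=2, TN=94 in a 100-sample matrix
        cm = np.zeros((5, 5), dtype=int)
        cm[0, 0], cm[0, 1] = 3, 1
        cm[1, 0], cm[1, 1] = 2, 94
        m = hb.class_metrics(cm, 1)
        assert m["SEN"] == pytest.approx(0.75)
        assert m["SPE"] == pytest.approx(0.9792, abs=1e-4)
        assert m["ACC"] == pytest.approx(0.97)
        assert m["Error"] == pytest.approx(0.03)

    @settings(max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000), cid=st.integers(1, 5))
    def test_acc_plus_error_is_one(self, seed, cid):
        cm = np.random.default_rng(seed).integers(0, 40, (5, 5))
        if cm.sum() == 0:
            return
        m = hb.class_metrics(cm, cid)
        assert m["ACC"] + m["Error"] == pytest.approx(1.0)

    def test_undefined_sensitivity_reported_as_none(self):
        cm = np.zeros((5, 5), dtype=int)
        cm[0, 0] = 10  # class 2 has no true samples
        assert hb.class_metrics(cm, 2)["SEN"] is None

    def test_matches_brute_force_oracle(self, random_pairs):
        y_true, y_pred = random_pairs
        cm = hb.confusion(y_true, y_pred)
        for cid in hb.CLASS_IDS:
            tp, tn, fp, fn = brute_force_counts(y_true, y_pred, cid)
            assert hb.one_vs_rest(cm, cid) == (tp, tn, fp, fn)

    def test_ovr_sums(self, random_pairs):
        cm = hb.confusion(*random_pairs)
        assert sum(hb.one_vs_rest(cm, c)[0] for c in hb.CLASS_IDS) == \
            np.trace(cm)
        for cid in hb.CLASS_IDS:
            assert sum(hb.one_vs_rest(cm, cid)) == cm.sum()


class TestBloodSen:
    def test_perfect_blood_prediction(self):
        cm = np.diag([0, 0, 4, 4, 0])
        assert hb.blood_sen(cm) == 1.0

    def test_no_cross_confusion_example(self):
        # venous TP=3 FN=1 (to healthy), arterial TP=1 FN=3 -> 4/8
        cm = np.zeros((5, 5), dtype=int)
        cm[2, 2], cm[2, 0] = 3, 1
        cm[3, 3], cm[3, 0] = 1, 3
        assert hb.blood_sen(cm) == pytest.approx(0.5)

    def test_cross_confusion_counts_as_merged_hit(self):
        cm = np.zeros((5, 5), dtype=int)
        cm[2, 3] = 5   # venous predicted arterial
        cm[3, 2] = 5   # arterial predicted venous
        assert hb.blood_sen(cm) == 1.0
        assert hb.blood_sen(cm, strict=True) == 0.0

    def test_between_per_class_sens_without_cross_confusion(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            cm = rng.integers(0, 20, (5, 5))
            cm[2, 3] = cm[3, 2] = 0
            sv = hb.class_metrics(cm, hb.VENOUS)["SEN"]
            sa = hb.class_metrics(cm, hb.ARTERIAL)["SEN"]
            if sv is None or sa is None:
                continue
            bs = hb.blood_sen(cm)
            assert min(sv, sa) - 1e-12 <= bs <= max(sv, sa) + 1e-12

    def test_no_blood_samples_undefined(self):
        cm = np.zeros((5, 5), dtype=int)
        cm[0, 0] = 3
        assert hb.blood_sen(cm) is None


class TestBandEfficiency:
    @pytest.mark.parametrize("oacc_pct,bands,expected", [
        (60.0, 25, 2.4),
        (53.0, 25, 2.12),
        (80.0, 128, 0.63),
        (49.0, 25, 1.96),
        (96.7, 826, 0.12),   # round-half-up of 0.11707
        (42.0, 1, 42.0),
    ])
    def test_published_comparison_rows(self, oacc_pct, bands, expected):
        assert hb.oacc_per_band(oacc_pct, bands) == expected

    def test_nonpositive_bands_rejected(self):
        with pytest.raises(ValueError):
            hb.oacc_per_band(50.0, 0)


class TestAggregate:
    def test_population_sd_and_none_skipping(self):
        out = hb.aggregate([0.5, 0.7, None, 0.6])
        assert out["n"] == 3
        assert out["mean"] == pytest.approx(0.6)
        assert out["sd"] == pytest.approx(np.std([0.5, 0.7, 0.6]))

    def test_report_roundtrip(self, random_pairs):
        rep = hb.MetricReport.from_predictions(*random_pairs)
        d = rep.to_dict()
        assert d["n"] == 1000
        assert d["oacc"] == pytest.approx(rep.oacc)
        assert set(d["per_class"]) == {"healthy", "tumor", "venous",
                                       "arterial", "dura"}
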