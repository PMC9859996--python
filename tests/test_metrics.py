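"""Area, boundary and classification metrics against hand values and
brute-force oracles."""

import numpy as np
import pytest

from busgate.metrics import (aggregate_report, area_metrics, boundary_metrics,
                             boundary_pixels, classification_metrics)


def _mask(shape, coords):
    m = np.zeros(shape, dtype=np.uint8)
    for r, c in coords:
        m[r, c] = 1
    return m


class TestAreaMetrics:
    def test_empty_empty_gives_perfect_generalized_dsc(self):
        z = np.zeros((8, 8), dtype=np.uint8)
        m = area_metrics(z, z)
        assert m.dsc == 1.0
        assert m.tpr is None and m.fpr is None and m.fnr is None
        assert m.undefined_reason is not None

    def test_false_positive_on_normal_image(self):
        # Am empty, |Ar| = 9 -> DSC = 1/(1+9)
        am = np.zeros((10, 10), dtype=np.uint8)
        ar = np.zeros((10, 10), dtype=np.uint8)
        ar[0:3, 0:3] = 1
        assert area_metrics(ar, am).dsc == pytest.approx(0.1)

    def test_disjoint_equal_masks(self):
        am = _mask((8, 8), [(0, 0), (0, 1), (1, 0), (1, 1)])
        ar = _mask((8, 8), [(5, 5), (5, 6), (6, 5), (6, 6)])
        m = area_metrics(ar, am)
        assert m.dsc == pytest.approx(1 / 9)
        assert m.ji == 0.0
        assert m.tpr == 0.0
        assert m.fpr == 1.0
        assert m.fnr == 1.0

    def test_identical_masks(self):
        am = _mask((8, 8), [(2, 2), (2, 3), (3, 2)])
        m = area_metrics(am, am)
        assert (m.dsc, m.ji, m.tpr, m.fpr, m.fnr) == (1.0, 1.0, 1.0, 0.0, 0.0)

    def test_tpr_plus_fnr_identity_on_random_pairs(self):
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(1000):
            am = (rng.uniform(0, 1, (12, 12)) > 0.6).astype(np.uint8)
            ar = (rng.uniform(0, 1, (12, 12)) > 0.6).astype(np.uint8)
            m = area_metrics(ar, am)
            if m.tpr is not None:
                assert m.tpr + m.fnr == pytest.approx(1.0, abs=1e-12)
                checked += 1
        assert checked > 900

    def test_fpr_can_exceed_one(self):
        am = _mask((8, 8), [(0, 0)])
        ar = np.zeros((8, 8), dtype=np.uint8)
        ar[4:7, 4:7] = 1
        assert area_metrics(ar, am).fpr == 9.0

    def test_dsc_converges_to_classical_dice_for_large_masks(self):
        """Generalized DSC -> 2*JI/(1+JI) as masks grow large."""
        am = np.zeros((80, 80), dtype=np.uint8)
        ar = np.zeros((80, 80), dtype=np.uint8)
        am[10:60, 10:60] = 1   # 2500 px
        ar[20:70, 15:65] = 1
        m = area_metrics(ar, am)
        classical = 2 * m.ji / (1 + m.ji)
        assert abs(m.dsc - classical) < 0.01

    def test_dsc_strictly_decreases_with_spurious_area(self):
        am = np.zeros((20, 20), dtype=np.uint8)
        am[5:10, 5:10] = 1
        prev = None
        for extra in range(0, 5):
            ar = am.copy()
            ar[15:16, 0:extra] = 1  # grow Ar without touching intersection
            d = area_metrics(ar, am).dsc
            if prev is not None:
                assert d < prev
            prev = d

    def test_flip_invariance(self):
        rng = np.random.default_rng(3)
        am = (rng.uniform(0, 1, (10, 10)) > 0.5).astype(np.uint8)
        ar = (rng.uniform(0, 1, (10, 10)) > 0.5).astype(np.uint8)
        m1 = area_metrics(ar, am)
        m2 = area_metrics(ar[:, ::-1], am[:, ::-1])
        assert m1 == m2

    def test_shape_and_value_validation(self):
        with pytest.raises(ValueError):
            area_metrics(np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            area_metrics(np.full((2, 2), 2), np.zeros((2, 2)))


def brute_force_boundary_distances(pred, true):
    """All-pairs oracle for HE/MAE on tiny masks."""
    a = boundary_pixels(pred).astype(float)
    b = boundary_pixels(true).astype(float)
    d_ab = [min(np.hypot(*(p - q)) for q in b) for p in a]
    d_ba = [min(np.hypot(*(q - p)) for p in a) for q in b]
    he = max(max(d_ab), max(d_ba))
    mae = np.mean(d_ab + d_ba)
    return he, mae


class TestBoundaryMetrics:
    def test_identical_masks_have_zero_error(self):
        m = _mask((10, 10), [(3, 3), (3, 4), (4, 3), (4, 4)])
        bm = boundary_metrics(m, m)
        assert bm.he == 0.0 and bm.mae == 0.0

    def test_single_pixel_masks_axis_aligned(self):
        a = _mask((10, 10), [(2, 2)])
        b = _mask((10, 10), [(2, 7)])
        bm = boundary_metrics(a, b)
        assert bm.he == 5.0 and bm.mae == 5.0

    def test_matches_brute_force_oracle_on_random_masks(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            shape = (int(rng.integers(4, 16)), int(rng.integers(4, 16)))
            pred = (rng.uniform(0, 1, shape) > 0.6).astype(np.uint8)
            true = (rng.uniform(0, 1, shape) > 0.6).astype(np.uint8)
            if not pred.any() or not true.any():
                continue
            bm = boundary_metrics(pred, true)
            he, mae = brute_force_boundary_distances(pred, true)
            assert bm.he == pytest.approx(he, abs=1e-9)
            assert bm.mae == pytest.approx(mae, abs=1e-9)
            assert bm.he >= bm.mae >= 0.0
            # symmetric in argument order
            sym = boundary_metrics(true, pred)
            assert sym.he == pytest.approx(bm.he) and \
                sym.mae == pytest.approx(bm.mae)

    def test_empty_mask_gives_flagged_undefined(self):
        m = _mask((6, 6), [(2, 2)])
        bm = boundary_metrics(np.zeros((6, 6), dtype=np.uint8), m)
        assert bm.he is None and bm.mae is None
        assert bm.undefined_reason == "empty mask"

    def test_pixel_spacing_scales_distances(self):
        a = _mask((10, 10), [(2, 2)])
        b = _mask((10, 10), [(2, 6)])
        bm = boundary_metrics(a, b, pixel_spacing=0.5)
        assert bm.he == pytest.approx(2.0)

    def test_border_pixels_count_as_contour(self):
        full = np.ones((5, 5), dtype=np.uint8)
        bp = boundary_pixels(full)
        assert len(bp) == 16  # perimeter of the 5x5 block


class TestClassificationMetrics:
    def test_perfect_separation(self):
        m = classification_metrics([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0])
        assert (m.auc, m.sensitivity, m.specificity, m.accuracy, m.f1) == \
            (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_all_tied_scores_have_half_auc(self):
        m = classification_metrics([0.4] * 6, [1, 0, 1, 0, 1, 0])
        assert m.auc == pytest.approx(0.5)

    def test_single_class_flags_auc_undefined(self):
        m = classification_metrics([0.9, 0.1], [1, 1])
        assert m.auc is None
        assert m.undefined_reason is not None

    def test_confusion_counts_hand_case(self):
        scores = [0.9, 0.4, 0.6, 0.2]
        labels = [1, 1, 0, 0]
        m = classification_metrics(scores, labels, threshold=0.5)
        # tp=1 fn=1 fp=1 tn=1
        assert m.sensitivity == 0.5
        assert m.specificity == 0.5
        assert m.accuracy == 0.5


class TestAggregateReport:
    def test_identical_values_give_zero_sd(self):
        report = aggregate_report([{"dsc": 0.8}] * 6, fold_ids=[0, 0, 1, 1,
                                                                2, 2])
        assert report.aggregate.loc["dsc", "mean"] == pytest.approx(0.8)
        assert report.aggregate.loc["dsc", "sd"] == pytest.approx(0.0,
                                                                  abs=1e-12)

    def test_two_fold_mean(self):
        report = aggregate_report([{"dsc": 0.6}, {"dsc": 1.0}],
                                  fold_ids=[0, 1])
        assert report.aggregate.loc["dsc", "mean"] == pytest.approx(0.8)

    def test_undefined_entries_excluded_and_counted(self):
        per_image = [{"tpr": 1.0}, {"tpr": None}, {"tpr": 0.5}]
        report = aggregate_report(per_image)
        assert report.excluded_counts["tpr"] == 1
        assert report.aggregate.loc["tpr", "mean"] == pytest.approx(0.75)

    def test_single_fold_sd_zero(self):
        report = aggregate_report([{"dsc": 0.7}, {"dsc": 0.9}])
        assert report.aggregate.loc["dsc", "sd"] == 0.0
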