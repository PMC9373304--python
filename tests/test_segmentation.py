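"""Thresholding methods and Jaccard/Dice overlap scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bleachdmd import dice, jaccard, multi_otsu_map, threshold_map
from bleachdmd.segmentation import THRESHOLD_METHODS, evaluate_modes


class TestJaccardDice:
    def test_identical_nonempty_masks(self):
        m = np.zeros((4, 4), bool)
        m[1:3, 1:3] = True
        assert jaccard(m, m) == 1.0
        assert dice(m, m) == 1.0

    def test_disjoint_nonempty_masks(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = b[3, 3] = True
        assert jaccard(a, b) == 0.0
        assert dice(a, b) == 0.0

    def test_hand_counted_example(self):
        a = np.zeros((2, 2), bool)
        b = np.zeros((2, 2), bool)
        a[0, 0] = a[0, 1] = True
        b[0, 1] = b[1, 1] = True
        assert jaccard(a, b) == pytest.approx(1 / 3)
        assert dice(a, b) == pytest.approx(0.5)

    def test_both_empty_defined_as_one(self):
        e = np.zeros((3, 3), bool)
        assert jaccard(e, e) == 1.0 and dice(e, e) == 1.0

    def test_empty_vs_nonempty_is_zero(self):
        e = np.zeros((3, 3), bool)
        f = e.copy()
        f[0, 0] = True
        assert jaccard(e, f) == 0.0 and dice(f, e) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.random((2, 8, 8)) > 0.5
        assert jaccard(a, b) == jaccard(b, a)
        assert dice(a, b) == dice(b, a)

    def test_complementing_both_masks_changes_jaccard(self):
        # guards against accidentally scoring the background
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, :2] = True
        b[0, 1:3] = True
        assert jaccard(~a, ~b) != jaccard(a, b)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            jaccard(np.zeros((2, 2), bool), np.zeros((3, 3), bool))
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2), bool), np.zeros((3, 3), bool))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_dice_jaccard_identity(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((10, 10)) > rng.random()
        b = rng.random((10, 10)) > rng.random()
        j, d = jaccard(a, b), dice(a, b)
        assert 0.0 <= j <= d <= 1.0
        assert abs(d - 2 * j / (1 + j)) <= 1e-12


class TestThresholdMap:
    def test_two_level_map_with_subbin_noise_segmented_exactly(self):
        rng = np.random.default_rng(0)
        region = np.zeros((40, 40), bool)
        region[10:30, 10:30] = True
        # noise far below the histogram bin width: each level occupies a
        # single bin and every histogram method cuts strictly between them
        m = np.where(region, 1.0, 0.0) + rng.normal(0, 1e-5, (40, 40))
        for method in set(THRESHOLD_METHODS) - {"minimum"}:
            assert np.array_equal(threshold_map(m, method=method).mask, region), method
        # two isolated spikes leave no interior histogram maxima for the
        # Minimum method's valley search: the documented error mode
        with pytest.raises(RuntimeError):
            threshold_map(m, method="minimum")

    def test_bimodal_map_with_visible_noise(self):
        rng = np.random.default_rng(0)
        region = np.zeros((40, 40), bool)
        region[10:30, 10:30] = True
        m = np.where(region, 1.0, 0.0) + rng.normal(0, 5e-3, (40, 40))
        for method in ("minimum", "isodata", "li", "mean", "triangle"):
            assert np.array_equal(threshold_map(m, method=method).mask, region), method
        # otsu's discrete argmax may sit one bin into the cluster tail
        from bleachdmd import jaccard

        assert jaccard(threshold_map(m, method="otsu").mask, region) >= 0.99

    def test_mean_method_hand_example(self):
        m = np.array([[0.0, 0.0], [0.0, 4.0]])
        seg = threshold_map(m, method="mean")
        assert seg.threshold == pytest.approx(1.0)
        assert seg.mask.sum() == 1 and seg.mask[1, 1]

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            threshold_map(np.ones((5, 5)))

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            threshold_map(np.random.default_rng(0).random((5, 5)), method="magic")

    def test_non_finite_map_rejected(self):
        m = np.ones((4, 4))
        m[0, 0] = np.inf
        m[1, 1] = 0.0
        with pytest.raises(ValueError):
            threshold_map(m)

    def test_threshold_within_map_range(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(20, 20))
        m[:10] += 5
        for method in THRESHOLD_METHODS:
            seg = threshold_map(m, method=method)
            assert m.min() <= seg.threshold <= m.max()


class TestMultiOtsu:
    def test_equal_thirds_exactly_separated(self):
        vals = np.repeat([0.0, 100.0, 200.0], 300)
        m = vals.reshape(30, 30)
        labels, thr = multi_otsu_map(m, 3)
        assert len(thr) == 2
        assert 0 < thr[0] < 100 < thr[1] < 200
        assert np.array_equal(np.unique(labels), [0, 1, 2])
        assert np.all((labels == 0) == (m == 0.0))
        assert np.all((labels == 2) == (m == 200.0))

    def test_two_classes_reduces_to_otsu(self):
        rng = np.random.default_rng(0)
        m = np.concatenate([rng.normal(0, 1, 500), rng.normal(10, 1, 500)]).reshape(20, 50)
        _, thr = multi_otsu_map(m, 2)
        otsu = threshold_map(m, method="otsu").threshold
        assert thr[0] == pytest.approx(otsu, abs=1e-9)

    def test_partially_bleached_frame_separates_four_classes(self, paper_sim):
        # by the 10th frame the three kinetic regions and the background
        # occupy four distinct intensity levels
        stack, truth = paper_sim
        labels, thr = multi_otsu_map(stack.frames[9].astype(float), 4)
        # every kinetic region plus background maps to its own dominant class
        owners = set()
        for mask in (*truth.masks.values(), truth.background_mask):
            vals, counts = np.unique(labels[mask], return_counts=True)
            owners.add(int(vals[np.argmax(counts)]))
        assert owners == {0, 1, 2, 3}

    def test_degenerate_histogram_rejected(self):
        with pytest.raises(ValueError):
            multi_otsu_map(np.ones((10, 10)), 3)

    def test_too_few_classes_rejected(self):
        with pytest.raises(ValueError):
            multi_otsu_map(np.random.default_rng(0).random((5, 5)), 1)


class TestEvaluateModes:
    def test_table_shape_and_identity(self, paper_sim, paper_model):
        _, truth = paper_sim
        table = evaluate_modes(paper_model, truth.masks, methods=("minimum", "otsu"))
        assert len(table) == 6  # 3 decaying modes x 2 methods
        assert set(table["region"]) == {"rectangle", "circle", "ellipse"}
        d_pred = 2 * table["jaccard"] / (1 + table["jaccard"])
        assert np.all(np.abs(table["dice"] - d_pred) <= 1e-12)

    def test_modes_match_distinct_regions(self, paper_sim, paper_model):
        _, truth = paper_sim
        table = evaluate_modes(paper_model, truth.masks, methods=("minimum",))
        assert len(set(table["region"])) == 3

    def test_no_decaying_modes_rejected(self):
        from bleachdmd import BleachStack, fit_dmd

        model = fit_dmd(BleachStack(np.full((6, 4, 4), 9.0)), rank=1)
        with pytest.raises(ValueError, match="decaying"):
            evaluate_modes(model, {"r": np.zeros((4, 4), bool)})
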