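"""Metric golden values, brute-force distance oracles, and invariances."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from dnatloss import metrics
from dnatloss.metrics import (assd, dice, ece, evaluate_dataset,
                              extract_boundary, fdr, hausdorff, iou,
                              mutual_information)


def mask_from(rows) -> np.ndarray:
    return np.array(rows, dtype=np.uint8)


def brute_force_distances(a, b):
    """All-pairs boundary distances, the independent oracle for HD/ASSD."""
    ba, bb = extract_boundary(a), extract_boundary(b)
    d = cdist(ba, bb)
    hd = max(d.min(axis=1).max(), d.min(axis=0).max())
    assd_val = (d.min(axis=1).sum() + d.min(axis=0).sum()) / (len(ba) + len(bb))
    return hd, assd_val


class TestOverlap:
    def test_identical_masks(self, rng):
        m = (rng.random((8, 8)) < 0.4).astype(np.uint8)
        assert dice(m, m) == 1.0 and iou(m, m) == 1.0 and fdr(m, m) == 0.0

    def test_disjoint_masks(self):
        a = mask_from([[1, 0], [0, 0]])
        b = mask_from([[0, 0], [0, 1]])
        assert dice(a, b) == 0.0 and iou(a, b) == 0.0

    def test_partial_overlap_counts(self):
        # |P|=4, |G|=4, overlap 2 → dice 0.5; |P∩G|=2, |P∪G|=6 → iou 1/3
        p = np.zeros((4, 4), dtype=np.uint8)
        g = np.zeros((4, 4), dtype=np.uint8)
        p[0, :4] = 1
        g[0, 2:] = 1
        g[1, :2] = 1
        assert dice(p, g) == 0.5
        assert iou(p, g) == pytest.approx(1 / 3)

    def test_fdr_counts(self):
        # TP=3, FP=1 → 0.25
        p = mask_from([[1, 1, 1, 1]])
        g = mask_from([[1, 1, 1, 0]])
        assert fdr(p, g) == 0.25

    def test_fdr_all_discoveries_false(self):
        p = mask_from([[0, 1], [0, 0]])
        g = mask_from([[0, 0], [1, 0]])
        assert fdr(p, g) == 1.0

    def test_empty_conventions(self):
        empty = np.zeros((3, 3), dtype=np.uint8)
        assert dice(empty, empty) == 1.0
        assert iou(empty, empty) == 1.0
        assert fdr(empty, np.ones((3, 3), dtype=np.uint8)) == 0.0

    def test_dice_iou_identity(self, rng):
        for _ in range(30):
            a = (rng.random((10, 10)) < 0.4).astype(np.uint8)
            b = (rng.random((10, 10)) < 0.4).astype(np.uint8)
            d, i = dice(a, b), iou(a, b)
            assert d == pytest.approx(2 * i / (1 + i))
            assert i <= d + 1e-12


class TestBoundary:
    def test_full_3x3_boundary_is_ring(self):
        b = extract_boundary(np.ones((3, 3), dtype=np.uint8))
        assert len(b) == 8
        assert [1, 1] not in b.tolist()

    def test_single_pixel_is_its_own_boundary(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        m[2, 2] = 1
        np.testing.assert_array_equal(extract_boundary(m), [[2, 2]])

    def test_strip_is_entirely_boundary(self):
        m = np.ones((1, 7), dtype=np.uint8)
        assert len(extract_boundary(m)) == 7

    def test_empty_mask_has_empty_boundary(self):
        assert len(extract_boundary(np.zeros((4, 4), dtype=np.uint8))) == 0


class TestDistances:
    def test_identical_masks_zero(self, rng):
        m = (rng.random((8, 8)) < 0.4).astype(np.uint8)
        m[2, 2] = 1
        assert hausdorff(m, m)[0] == 0.0
        assert assd(m, m)[0] == 0.0

    def test_single_pixels_pythagorean(self):
        a = np.zeros((6, 6), dtype=np.uint8)
        b = np.zeros((6, 6), dtype=np.uint8)
        a[0, 0] = 1
        b[3, 4] = 1
        assert hausdorff(a, b)[0] == 5.0
        assert assd(a, b)[0] == 5.0

    def test_symmetry_and_assd_below_hd(self, rng):
        for _ in range(25):
            a = (rng.random((12, 12)) < 0.35).astype(np.uint8)
            b = (rng.random((12, 12)) < 0.35).astype(np.uint8)
            if not a.any() or not b.any():
                continue
            hd_ab, _ = hausdorff(a, b)
            hd_ba, _ = hausdorff(b, a)
            as_ab, _ = assd(a, b)
            assert hd_ab == hd_ba
            assert as_ab <= hd_ab + 1e-12

    def test_matches_brute_force_oracle(self, rng):
        checked = 0
        while checked < 25:
            a = (rng.random((16, 16)) < 0.3).astype(np.uint8)
            b = (rng.random((16, 16)) < 0.3).astype(np.uint8)
            if not a.any() or not b.any():
                continue
            hd_o, assd_o = brute_force_distances(a, b)
            assert hausdorff(a, b)[0] == pytest.approx(hd_o, abs=1e-12)
            assert assd(a, b)[0] == pytest.approx(assd_o, abs=1e-12)
            checked += 1

    def test_translation_invariance(self):
        a = np.zeros((16, 16), dtype=np.uint8)
        b = np.zeros((16, 16), dtype=np.uint8)
        a[4:7, 4:7] = 1
        b[5:9, 4:6] = 1
        base = (hausdorff(a, b)[0], assd(a, b)[0])
        shifted = (hausdorff(np.roll(a, 3, axis=1), np.roll(b, 3, axis=1))[0],
                   assd(np.roll(a, 3, axis=1), np.roll(b, 3, axis=1))[0])
        assert base == shifted

    def test_empty_boundary_returns_diagonal_and_flag(self):
        empty = np.zeros((3, 4), dtype=np.uint8)
        full = np.ones((3, 4), dtype=np.uint8)
        val, flagged = hausdorff(empty, full)
        assert flagged and val == pytest.approx(5.0)
        val, flagged = assd(full, empty)
        assert flagged and val == pytest.approx(5.0)


class TestECE:
    def test_perfectly_confident_and_correct(self):
        assert ece(np.ones((4, 4)), np.ones((4, 4))) == 0.0

    def test_confident_but_half_wrong(self):
        gt = np.zeros((2, 2))
        gt[0] = 1.0
        assert ece(np.ones((2, 2)), gt) == pytest.approx(0.5)

    def test_permutation_invariant(self, rng):
        p = rng.random(100)
        g = (rng.random(100) < 0.5).astype(int)
        perm = rng.permutation(100)
        assert ece(p, g) == pytest.approx(ece(p[perm], g[perm]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ece(np.zeros((0,)), np.zeros((0,)))


class TestMutualInformation:
    def test_perfect_balanced_prediction_is_one_bit(self):
        m = np.zeros((4, 4), dtype=np.uint8)
        m[:2] = 1
        assert mutual_information(m, m) == pytest.approx(1.0)

    def test_constant_prediction_is_zero(self, rng):
        g = (rng.random((6, 6)) < 0.5).astype(np.uint8)
        assert mutual_information(np.zeros((6, 6), dtype=np.uint8), g) == 0.0

    def test_symmetric(self, rng):
        a = (rng.random((8, 8)) < 0.4).astype(np.uint8)
        b = (rng.random((8, 8)) < 0.4).astype(np.uint8)
        assert mutual_information(a, b) == pytest.approx(mutual_information(b, a))


class TestEvaluateDataset:
    def _pair(self, rng, n=8):
        g = (rng.random((n, n)) < 0.4).astype(np.uint8)
        g[3, 3] = 1
        p = np.clip(g + rng.normal(0, 0.2, (n, n)), 0, 1)
        return p, (p > 0.5).astype(np.uint8), g

    def test_single_pair_equals_per_image(self, rng):
        pair = self._pair(rng)
        rep = evaluate_dataset([pair])
        per = metrics.evaluate_image(*pair)
        assert rep.dice == per["dice"] and rep.hd_px == per["hd_px"]
        assert rep.n_images == 1

    def test_mean_of_per_image_metrics(self, rng):
        g = np.zeros((6, 6), dtype=np.uint8)
        g[2:4, 2:4] = 1
        perfect = (g.astype(float), g, g)
        disjoint_pred = np.zeros((6, 6), dtype=np.uint8)
        disjoint_pred[0, 0] = 1
        wrong = (disjoint_pred.astype(float), disjoint_pred, g)
        rep = evaluate_dataset([perfect, wrong])
        assert rep.dice == pytest.approx(0.5)

    def test_pooled_ece_differs_from_mean_of_per_image(self):
        # image A: 4 px at conf 1.0, all correct; image B: 16 px at conf
        # 1.0, half correct.  Pooling weights B 4× more than averaging.
        a_p, a_g = np.ones((2, 2)), np.ones((2, 2))
        b_p = np.ones((4, 4))
        b_g = np.zeros((4, 4))
        b_g[:2] = 1
        rep = evaluate_dataset([(a_p, a_g.astype(np.uint8), a_g),
                                (b_p, (b_p > 0.5).astype(np.uint8), b_g)])
        pooled = (0 * 4 + 0.5 * 16) / 20
        mean_of = (0.0 + 0.5) / 2
        assert rep.ece == pytest.approx(pooled)
        assert rep.ece != pytest.approx(mean_of)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            evaluate_dataset([])

    def test_report_schema(self, rng):
        rep = evaluate_dataset([self._pair(rng)])
        d = rep.to_dict()
        for key in ("dice", "iou", "fdr", "hd_px", "assd_px", "ece", "mi_bits",
                    "empty_boundary_images"):
            assert key in d
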