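"""Instance and calibration metrics vs independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ringseg.metrics import (
    adapted_rand_error,
    boundary_errors,
    ence,
    evaluate_pair,
    iou,
    match_instances,
    mean_average_recall,
    panoptic_quality,
)


# ---------------------------------------------------------------------------
# brute-force oracles (straight from the definitions, O(labels^2) loops)
# ---------------------------------------------------------------------------

def oracle_iou_table(gt, pred):
    out = {}
    for j in range(1, gt.max() + 1):
        for i in range(1, pred.max() + 1):
            a, b = gt == j, pred == i
            union = (a | b).sum()
            out[(j, i)] = (a & b).sum() / union if union else 0.0
    return out


def oracle_arand(gt, pred, alpha=0.5):
    keep = gt > 0
    g, p = gt[keep], pred[keep]
    total = keep.sum()
    num = 0.0
    for j in np.unique(g):
        for i in np.unique(p):
            pij = ((g == j) & (p == i)).sum() / total
            num += pij**2
    s2 = sum(((p == i).sum() / total) ** 2 for i in np.unique(p))
    t2 = sum(((g == j).sum() / total) ** 2 for j in np.unique(g))
    return 1 - num / (alpha * s2 + (1 - alpha) * t2)


def random_labeling(rng, shape=(32, 32), max_instances=6):
    """Random blobby labeling via nearest-seed assignment."""
    n = rng.integers(1, max_instances + 1)
    seeds = rng.uniform(0, shape[0], size=(n, 2))
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                         indexing="ij")
    d = np.stack([np.hypot(rr - s[0], cc - s[1]) for s in seeds])
    labels = d.argmin(axis=0) + 1
    labels[d.min(axis=0) > rng.uniform(8, 25)] = 0  # background fringe
    return labels.astype(np.int32)


@pytest.mark.parametrize("seed", range(4))
def test_metrics_agree_with_bruteforce_oracles(seed):
    rng = np.random.default_rng(seed)
    for _ in range(25):
        gt = random_labeling(rng)
        pred = random_labeling(rng)
        table = oracle_iou_table(gt, pred)
        # matching
        matches, fn, fp = match_instances(gt, pred)
        expected_matches = {(j, i) for (j, i), v in table.items() if v > 0.5}
        assert {(j, i) for j, i, _ in matches} == expected_matches
        # mAR closed form
        k = gt.max()
        best = [max((table[(j, i)] for i in range(1, pred.max() + 1)),
                    default=0.0) for j in range(1, k + 1)]
        expected_mar = 2 / k * sum(max(v - 0.5, 0.0) for v in best)
        assert mean_average_recall(gt, pred) == pytest.approx(expected_mar)
        # ARAND
        assert adapted_rand_error(gt, pred) == pytest.approx(
            oracle_arand(gt, pred), abs=1e-12)
        # PQ from the oracle matching
        tp = len(expected_matches)
        if tp:
            sq = np.mean([table[m] for m in expected_matches])
            rq = tp / (tp + 0.5 * (pred.max() - tp) + 0.5 * (k - tp))
            pq, sq_got, rq_got = panoptic_quality(gt, pred)
            assert (pq, sq_got, rq_got) == pytest.approx((sq * rq, sq, rq))


def test_perfect_prediction_identities(simple_sample):
    _, mask = simple_sample
    g = mask.labels
    assert mean_average_recall(g, g) == pytest.approx(1.0)
    assert adapted_rand_error(g, g) == pytest.approx(0.0)
    assert panoptic_quality(g, g) == pytest.approx((1.0, 1.0, 1.0))
    mae, medae, _ = boundary_errors(g, g)
    assert mae == 0.0 and medae == 0.0


class TestIoU:
    def test_identical_and_disjoint(self):
        a = np.zeros((10, 10), bool)
        a[2:6] = True
        assert iou(a, a) == 1.0
        assert iou(a, ~a) == 0.0
        assert iou(np.zeros((4, 4), bool), np.zeros((4, 4), bool)) == 0.0

    def test_rectangles_one_third(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a[0:10, 0:10] = True
        b[5:15, 0:10] = True
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            iou(np.ones((3, 3)), np.ones((4, 4)))


class TestClosedForms:
    def test_mar_single_instance_075(self):
        gt = np.zeros((20, 20), np.int32)
        gt[0:16, 0:10] = 1          # 160 px
        pred = np.zeros_like(gt)
        pred[0:16, 0:10] = 1
        pred[0:16, 0] = 0           # drop a 16-px column: IoU = 144/160 = 0.9
        assert mean_average_recall(gt, pred) == pytest.approx(2 * 0.4)

    def test_mar_below_threshold_zero(self):
        gt = np.zeros((10, 10), np.int32)
        gt[:5] = 1
        pred = np.zeros_like(gt)
        pred[8:] = 1
        assert mean_average_recall(gt, pred) == 0.0

    def test_arand_split_segment_one_third(self):
        gt = np.ones((10, 10), np.int32)
        pred = np.ones((10, 10), np.int32)
        pred[:, 5:] = 2
        assert adapted_rand_error(gt, pred, alpha=0.5) == pytest.approx(1 / 3)

    def test_pq_worked_example(self):
        """One TP at IoU 0.8, one FP, one FN -> SQ 0.8, RQ 0.5, PQ 0.4."""
        gt = np.zeros((30, 30), np.int32)
        pred = np.zeros_like(gt)
        gt[0:10, 0:10] = 1          # matched by pred 1 at IoU 100/125 = 0.8
        pred[0:10, 0:10] = 1
        pred[10:15, 0:5] = 1
        gt[20:25, 20:25] = 2        # FN
        pred[0:5, 20:25] = 2        # FP
        pq, sq, rq = panoptic_quality(gt, pred)
        assert (sq, rq, pq) == pytest.approx((0.8, 0.5, 0.4))

    def test_no_tp_convention(self):
        gt = np.zeros((10, 10), np.int32)
        gt[:3] = 1
        pred = np.zeros_like(gt)
        assert panoptic_quality(gt, pred) == (0.0, 0.0, 0.0)


class TestBoundaryErrors:
    def test_offset_circles(self):
        rr, cc = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        rad = np.hypot(rr - 32, cc - 32)
        gt = (rad <= 10).astype(np.int32)
        pred = (rad <= 12).astype(np.int32)
        mae, medae, _ = boundary_errors(gt, pred, [(1, 1, 0.8)])
        assert mae == pytest.approx(2.0, abs=0.5)
        assert medae == pytest.approx(2.0, abs=0.5)

    def test_outlier_multiset(self):
        gt = np.zeros((8, 8), np.int32)
        gt[4, 4] = 1
        pts = np.tile([[4.0, 6.0]], (99, 1))          # 99 points at distance 2
        pts = np.r_[pts, [[4.0, 54.0]]]               # one outlier at 50
        mae, medae, _ = boundary_errors(gt, gt, [(1, 1, 1.0)],
                                        pred_points={1: pts})
        assert medae == pytest.approx(2.0)
        assert mae == pytest.approx(2.48)

    def test_no_matches_reported_absent(self):
        gt = np.zeros((8, 8), np.int32)
        gt[2:4] = 1
        pred = np.zeros_like(gt)
        mae, medae, ae = boundary_errors(gt, pred, [])
        assert mae is None and medae is None and ae == []


class TestEnce:
    def test_perfectly_calibrated_constant_zero(self):
        sigma = np.full(200, 2.0)
        errors = np.full(200, 2.0)  # RMSE = 2 but mVAR = 4
        assert ence(sigma, errors, n_bins=10, variant="standard") == pytest.approx(0.0)
        sigma1 = np.ones(200)
        errors1 = np.ones(200)      # mVAR = RMSE = 1: both variants zero
        for variant in ("variance", "standard"):
            assert ence(sigma1, errors1, n_bins=10, variant=variant) == pytest.approx(0.0)

    def test_variance_vs_standard_divergence(self):
        """sigma^2 = c and RMSE^2 = c per bin: the variance form gives
        |c - sqrt(c)|/c while the dimensionally consistent form gives 0."""
        c = 4.0
        sigma = np.full(100, np.sqrt(c))
        errors = np.full(100, np.sqrt(c))
        variance = ence(sigma, errors, n_bins=10, variant="variance")
        standard = ence(sigma, errors, n_bins=10, variant="standard")
        assert variance == pytest.approx(abs(c - np.sqrt(c)) / c)
        assert standard == pytest.approx(0.0)

    def test_doubling_sigma_breaks_calibration(self):
        rng = np.random.default_rng(0)
        b = rng.uniform(0.5, 2.0, 2000)
        errors = np.abs(rng.laplace(0, b))
        sigma = np.sqrt(2) * b  # calibrated
        base = ence(sigma, errors, n_bins=20, variant="standard")
        doubled = ence(2 * sigma, errors, n_bins=20, variant="standard")
        assert doubled > base

    def test_fewer_points_than_bins_reduces_bins(self):
        val = ence(np.ones(7), np.ones(7), n_bins=100)
        assert np.isfinite(val)

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            ence(np.ones(5), np.ones(6))


@settings(deadline=None, max_examples=20)
@given(st.integers(0, 2**32 - 1))
def test_relabeling_invariance(seed):
    """Permuting instance ids changes no metric."""
    rng = np.random.default_rng(seed)
    gt = random_labeling(rng)
    pred = random_labeling(rng)
    perm = rng.permutation(pred.max()) + 1
    pred2 = np.zeros_like(pred)
    for old, new in enumerate(perm, start=1):
        pred2[pred == old] = new
    assert mean_average_recall(gt, pred) == pytest.approx(
        mean_average_recall(gt, pred2))
    assert adapted_rand_error(gt, pred) == pytest.approx(
        adapted_rand_error(gt, pred2))
    assert panoptic_quality(gt, pred) == pytest.approx(
        panoptic_quality(gt, pred2))


def test_evaluate_pair_report_consistency(simple_sample):
    _, mask = simple_sample
    rep = evaluate_pair(mask.labels, mask.labels)
    assert rep.pq == pytest.approx(rep.sq * rep.rq, abs=1e-12)
    assert rep.tp == mask.n_rings and rep.fp == rep.fn == 0
    d = rep.to_dict()
    assert d["mAR"] == 1.0 and d["ARAND"] == pytest.approx(0.0)
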