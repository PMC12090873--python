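"""Instance-segmentation and calibration metrics.

Implements IoU, instance matching at IoU > 0.5, mean average recall
(mAR), adapted Rand error (ARAND), panoptic quality (PQ = SQ x RQ),
boundary MAE/MedAE, and the expected normalized calibration error
(ENCE).  Label 0 (background/non-xylem) is excluded from all instance
metrics: rings are the instances.

ENCE note: two variants are implemented.  The default "variance"
form compares the mean predicted variance (mVAR) directly against the
RMSE per bin; the dimensionally consistent "standard" form compares
sqrt(mVAR) against the RMSE.  Reports record which one was used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

__all__ = [
    "MetricsReport",
    "iou",
    "match_instances",
    "mean_average_recall",
    "adapted_rand_error",
    "panoptic_quality",
    "boundary_errors",
    "ence",
    "evaluate_pair",
]

logger = logging.getLogger(__name__)


def _labels_of(mask):
    from .io import InstanceMask

    return mask.labels if isinstance(mask, InstanceMask) else np.asarray(mask)


def iou(y, y_hat) -> float:
    """Intersection over union of two binary masks (0 when both empty)."""
    y = np.asarray(y, dtype=bool)
    y_hat = np.asarray(y_hat, dtype=bool)
    if y.shape != y_hat.shape:
        raise ValueError("shape mismatch")
    union = (y | y_hat).sum()
    if union == 0:
        return 0.0
    return float((y & y_hat).sum() / union)


def _contingency(gt, pred):
    """Pixel counts n[j, i] for GT segment j x pred segment i (incl. 0)."""
    gt = _labels_of(gt).ravel()
    pred = _labels_of(pred).ravel()
    ng, np_ = int(gt.max()) + 1, int(pred.max()) + 1
    table = np.bincount(gt * np_ + pred, minlength=ng * np_).reshape(ng, np_)
    return table


def _pair_ious(gt, pred):
    """IoU matrix between all GT rings and predicted rings."""
    table = _contingency(gt, pred)
    inter = table[1:, 1:].astype(float)
    gt_sizes = table[1:, :].sum(axis=1, keepdims=True)
    pred_sizes = table[:, 1:].sum(axis=0, keepdims=True)
    union = gt_sizes + pred_sizes - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out  # (n_gt, n_pred)


def match_instances(gt, pred, threshold: float = 0.5):
    """One-to-one matching of instances with IoU > threshold.

    Returns (matches, fn_labels, fp_labels) where matches is a list of
    (gt_label, pred_label, iou).  At threshold >= 0.5 matches are
    automatically unique.
    """
    ious = _pair_ious(gt, pred)
    matches = []
    matched_gt, matched_pred = set(), set()
    if ious.size:
        for j, i in zip(*np.nonzero(ious > threshold)):
            matches.append((j + 1, i + 1, float(ious[j, i])))
            matched_gt.add(j + 1)
            matched_pred.add(i + 1)
    n_gt, n_pred = ious.shape
    fn = [j for j in range(1, n_gt + 1) if j not in matched_gt]
    fp = [i for i in range(1, n_pred + 1) if i not in matched_pred]
    return matches, fn, fp


def mean_average_recall(gt, pred) -> float:
    """mAR = (2/k) * sum_i max(IoU(gt_i) - 0.5, 0), IoU(gt_i) taken
    against each GT instance's best-overlapping prediction."""
    ious = _pair_ious(gt, pred)
    k = ious.shape[0]
    if k == 0:
        raise ValueError("no ground-truth instances")
    best = ious.max(axis=1) if ious.shape[1] else np.zeros(k)
    return float(2.0 / k * np.maximum(best - 0.5, 0.0).sum())


def adapted_rand_error(gt, pred, alpha: float = 0.5) -> float:
    """ARAND = 1 - sum_ij p_ij^2 / (a*sum s_k^2 + (1-a)*sum t_k^2).

    p_ij is the fraction of evaluated pixels jointly in pred segment i
    and GT segment j; s/t are the row/column marginals.  Pixels that
    are background in the ground truth are excluded; predicted label 0
    within the evaluated region counts as its own (unmatched) segment.
    """
    gt_l = _labels_of(gt)
    pred_l = _labels_of(pred)
    keep = gt_l > 0
    if not keep.any():
        raise ValueError("empty ground-truth foreground")
    table = _contingency(gt_l[keep], pred_l[keep]).astype(float)
    p = table / table.sum()
    s = p.sum(axis=0)  # per pred segment
    t = p.sum(axis=1)  # per GT segment
    num = (p**2).sum()
    den = alpha * (s**2).sum() + (1 - alpha) * (t**2).sum()
    return float(1.0 - num / den)


def panoptic_quality(gt, pred, threshold: float = 0.5):
    """(PQ, SQ, RQ): SQ = mean matched IoU, RQ = |TP|/(|TP|+0.5|FP|+0.5|FN|)."""
    matches, fn, fp = match_instances(gt, pred, threshold)
    tp = len(matches)
    if tp == 0:
        return 0.0, 0.0, 0.0
    sq = float(np.mean([m[2] for m in matches]))
    rq = tp / (tp + 0.5 * len(fp) + 0.5 * len(fn))
    return sq * rq, sq, rq


def instance_contour(binary: np.ndarray) -> np.ndarray:
    """(K, 2) coordinates of the 8-connected outer contour pixels."""
    binary = np.asarray(binary, dtype=bool)
    er = ndi.binary_erosion(binary, structure=ndi.generate_binary_structure(2, 1))
    rows, cols = np.nonzero(binary & ~er)
    return np.stack([rows, cols], axis=1)


def boundary_errors(gt, pred, matching=None, pred_points=None):
    """Per-point boundary absolute errors over matched instances.

    For each matched pair, AE = Euclidean distance from each predicted
    boundary point to the closest ground-truth contour pixel (full
    resolution).  Predicted points default to the prediction's mask
    contour; ``pred_points`` may supply polyline vertices instead
    (dict: pred label -> (K, 2) array).  Returns (MAE, MedAE, ae_list);
    (None, None, []) when nothing matched.
    """
    gt_l = _labels_of(gt)
    pred_l = _labels_of(pred)
    if matching is None:
        matching, _, _ = match_instances(gt_l, pred_l)
    all_ae = []
    for gt_lab, pred_lab, _ in matching:
        gt_contour = instance_contour(gt_l == gt_lab)
        if pred_points is not None and pred_lab in pred_points:
            pts = np.asarray(pred_points[pred_lab], dtype=float)
        else:
            pts = instance_contour(pred_l == pred_lab).astype(float)
        if len(gt_contour) == 0 or len(pts) == 0:
            continue
        tree = cKDTree(gt_contour)
        d, _ = tree.query(pts)
        all_ae.append(d)
    if not all_ae:
        return None, None, []
    ae = np.concatenate(all_ae)
    return float(ae.mean()), float(np.median(ae)), ae


def ence(sigma, errors, n_bins: int = 100, variant: str = "variance") -> float:
    """Expected normalized calibration error over uncertainty bins.

    Points are sorted by predicted sigma (stable, so ties keep input
    order) and split into ``n_bins`` equal-count bins; per bin,
    mVAR = mean sigma^2 and RMSE = root-mean-square error.  The
    "variance" variant averages |mVAR - RMSE| / mVAR per bin; the
    "standard" variant averages |sqrt(mVAR) - RMSE| / sqrt(mVAR) (the
    dimensionally consistent form).  When fewer
    points than bins are given, the bin count is reduced.
    """
    sigma = np.asarray(sigma, dtype=float).ravel()
    errors = np.asarray(errors, dtype=float).ravel()
    if sigma.size != errors.size:
        raise ValueError("sigma/error arrays must align")
    t = sigma.size
    if t == 0:
        raise ValueError("no points")
    if t < n_bins:
        logger.warning("ENCE: %d points < %d bins; using %d bins", t, n_bins, t)
        n_bins = t
    order = np.argsort(sigma, kind="stable")
    bins_sigma = np.array_split(sigma[order], n_bins)
    bins_err = np.array_split(errors[order], n_bins)
    total = 0.0
    for bs, be in zip(bins_sigma, bins_err):
        mvar = (bs**2).mean()
        rmse = np.sqrt((be**2).mean())
        if variant == "variance":
            total += abs(mvar - rmse) / mvar
        elif variant == "standard":
            total += abs(np.sqrt(mvar) - rmse) / np.sqrt(mvar)
        else:
            raise ValueError("variant must be 'variance' or 'standard'")
    return float(total / n_bins)


@dataclass
class MetricsReport:
    """Instance and calibration metrics for one prediction-label pair."""

    mar: float
    arand: float
    pq: float
    sq: float
    rq: float
    mae: float | None
    medae: float | None
    ence: float | None
    n_gt: int
    n_pred: int
    tp: int
    fp: int
    fn: int
    ence_variant: str = "variance"

    def to_dict(self):
        return {
            "mAR": self.mar, "ARAND": self.arand, "PQ": self.pq,
            "SQ": self.sq, "RQ": self.rq, "MAE": self.mae,
            "MedAE": self.medae, "ENCE": self.ence,
            "n_gt": self.n_gt, "n_pred": self.n_pred,
            "TP": self.tp, "FP": self.fp, "FN": self.fn,
            "ENCE_variant": self.ence_variant,
        }


def evaluate_pair(gt, pred, pred_points=None, point_sigmas=None,
                  n_bins: int = 100, ence_variant: str = "variance"):
    """Full MetricsReport for one (ground truth, prediction) pair.

    ``pred_points``/``point_sigmas`` (dicts keyed by predicted label)
    supply per-ring boundary polyline vertices and their per-point
    sigmas; when given, MAE/MedAE/ENCE are computed from those points,
    otherwise from mask contours (and ENCE is absent).
    """
    gt_l = _labels_of(gt)
    pred_l = _labels_of(pred)
    matches, fn, fp = match_instances(gt_l, pred_l)
    pq, sq, rq = panoptic_quality(gt_l, pred_l)
    mae, medae, ae = boundary_errors(gt_l, pred_l, matches, pred_points)

    ence_val = None
    if pred_points is not None and point_sigmas is not None and matches:
        sig_all, err_all = [], []
        for gt_lab, pred_lab, _ in matches:
            if pred_lab not in pred_points or point_sigmas.get(pred_lab) is None:
                continue
            gt_contour = instance_contour(gt_l == gt_lab)
            pts = np.asarray(pred_points[pred_lab], dtype=float)
            if len(gt_contour) == 0 or len(pts) == 0:
                continue
            d, _ = cKDTree(gt_contour).query(pts)
            sig_all.append(np.asarray(point_sigmas[pred_lab], dtype=float))
            err_all.append(d)
        if sig_all:
            ence_val = ence(
                np.concatenate(sig_all), np.concatenate(err_all),
                n_bins=n_bins, variant=ence_variant,
            )

    return MetricsReport(
        mar=mean_average_recall(gt_l, pred_l),
        arand=adapted_rand_error(gt_l, pred_l),
        pq=pq, sq=sq, rq=rq, mae=mae, medae=medae, ence=ence_val,
        n_gt=int(gt_l.max()), n_pred=int(pred_l.max()),
        tp=len(matches), fp=len(fp), fn=len(fn),
        ence_variant=ence_variant,
    )
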