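"""Iterative-unrolling training for the radial regression model.

Rather than running K consecutive iterative steps inside one training
step, the K steps are spread over K epochs: each training step runs a
single forward pass and saves its predicted boundary to disk; the next
epoch's data loading reads that boundary and builds the next polar
image, so the sample is effectively one iterative step further.  Every
(image, ring-start) sample is duplicated K times with staggered
starting epochs, so every epoch mixes records at different iteration
steps from different images; after K epochs a record resets to its
ground-truth ring start.  Boundary files written in epoch e are only
read in epoch e+1 (file names carry the epoch parity), which avoids
read/write races.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .config import RunConfig
from .io import InstanceMask
from .polar import (
    BoundaryPolyline,
    adaptive_angular_resolution,
    build_polar_grid,
    ds_to_full,
    estimate_ring_width,
    interpolate_polar,
)
from .radial_reg import (
    RegressionNet,
    l1_loss,
    laplace_nll_loss,
    normalize_target,
)
from .semantic import downscale_image, normalize_image, semantic_forward
from .synthetic import ground_truth_boundaries, pith_boundary

__all__ = [
    "radial_targets",
    "precompute_semantic",
    "SemanticCache",
    "UnrollState",
    "unrolled_epoch",
    "train_regression",
]

logger = logging.getLogger(__name__)


def radial_targets(boundary: BoundaryPolyline, gt_mask: InstanceMask, grid,
                   p: float, factor: int = 4,
                   absent_fraction: float = 0.5):
    """Ground-truth row distances D to the next ring along each ray.

    The current ring k is identified by majority vote of the labels
    just inside the boundary; the target along each column is the
    first crossing out of the union of rings 1..k+1 (so on arcs where
    ring k+1 wedges to zero width the target is the following
    boundary).  Columns with no crossing within N rows are masked out.
    Returns (d_rows, valid) or None ("absent") when no next ring
    exists or fewer than ``1 - absent_fraction`` of columns have one.
    """
    n, m = grid.shape[1], grid.shape[2]
    labels = gt_mask.labels

    # current ring: sample 1 px inside the boundary (full-res labels)
    dirs = boundary.directions()
    inset = boundary.center[:, None] + dirs * (boundary.radii - 1.0)[None, :]
    inset_full = ds_to_full(inset, factor)
    inside_labels = _sample_labels(labels, inset_full)
    # majority label just inside; 0 means the start is the pith boundary
    k = int(np.bincount(inside_labels).argmax())
    if k >= gt_mask.n_rings:
        return None  # outermost ring: no next ring to regress to

    grid_full = ds_to_full(grid.reshape(2, -1), factor)
    lab = _sample_labels(labels, grid_full).reshape(n, m)
    member = (lab >= 1) & (lab <= k + 1)
    # rays start on (or just inside of) the current boundary, so find the
    # first exit *after* first entering the union of rings 1..k+1 — row 0
    # may still sample the pith or sit on the interface
    entered = member.any(axis=0)
    first_enter = member.argmax(axis=0)
    rows_idx = np.arange(n)[:, None]
    left = ~member & (rows_idx >= first_enter[None, :])
    has_exit = left.any(axis=0)
    first_exit = left.argmax(axis=0)
    d = np.maximum(first_exit - 0.5, 0.0)
    # columns already past ring k+1 at row 0 (ring k+1 wedges to zero
    # width there): the next boundary coincides with the current one
    beyond = ~entered & (lab[0] > k + 1)
    d = np.where(beyond, 0.0, d)
    valid = (entered & has_exit) | beyond
    if valid.mean() < absent_fraction:
        return None
    return d, valid


def _sample_labels(labels, coords):
    r = np.clip(np.round(coords[0]).astype(int), 0, labels.shape[0] - 1)
    c = np.clip(np.round(coords[1]).astype(int), 0, labels.shape[1] - 1)
    inside = (
        (coords[0] >= -0.5) & (coords[0] < labels.shape[0] - 0.5)
        & (coords[1] >= -0.5) & (coords[1] < labels.shape[1] - 0.5)
    )
    out = labels[r, c].copy()
    out[~inside] = 0
    return out


# ---------------------------------------------------------------------------
# semantic cache
# ---------------------------------------------------------------------------

@dataclass
class SemanticCache:
    """Per-image cached inputs for regression training."""

    image_ds: np.ndarray        # (3, h, w) normalized
    background_logit: np.ndarray
    boundary_logit: np.ndarray
    pith_center: np.ndarray | None
    pith_radii: np.ndarray | None

    @property
    def boundary_prob(self):
        return 1.0 / (1.0 + np.exp(-self.boundary_logit))

    @property
    def background_prob(self):
        return 1.0 / (1.0 + np.exp(-self.background_logit))


def _model_version(seg_model, config):
    tag = sum(float(np.abs(p.data).sum()) for p in seg_model.parameters())
    return np.array([tag, config.downscale], dtype=np.float64)


def precompute_semantic(samples, seg_model, cache_dir, config: RunConfig = None):
    """Run the segmentation model once per image and cache to disk.

    ``samples`` is a list of (id, RingImage, InstanceMask).  A second
    call with a warm cache performs zero model forwards; stale or
    corrupted entries are recomputed.  Returns {id: SemanticCache}.
    """
    config = config or RunConfig()
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    version = _model_version(seg_model, config)
    caches = {}
    for sample_id, image, mask in samples:
        path = cache_dir / f"{sample_id}.npz"
        entry = _load_cache_entry(path, version)
        if entry is None:
            out = semantic_forward(image, seg_model, config)
            ds = downscale_image(image.pixels, config.downscale)
            try:
                from .semantic import extract_pith

                center, pith = extract_pith(out, config.pith_threshold)
                p_center, p_radii = pith.center, pith.radii
            except Exception:
                p_center = p_radii = None
            entry = SemanticCache(
                image_ds=normalize_image(ds),
                background_logit=out.logit("background"),
                boundary_logit=out.logit("boundary"),
                pith_center=p_center,
                pith_radii=p_radii,
            )
            payload = {
                "version": version,
                "image_ds": entry.image_ds,
                "background_logit": entry.background_logit,
                "boundary_logit": entry.boundary_logit,
            }
            if p_center is not None:
                payload["pith_center"] = p_center
                payload["pith_radii"] = p_radii
            np.savez(path, **payload)
        caches[sample_id] = entry
    return caches


def _load_cache_entry(path, version):
    if not Path(path).exists():
        return None
    try:
        with np.load(path) as data:
            if not np.allclose(data["version"], version):
                return None
            return SemanticCache(
                image_ds=data["image_ds"],
                background_logit=data["background_logit"],
                boundary_logit=data["boundary_logit"],
                pith_center=data["pith_center"] if "pith_center" in data else None,
                pith_radii=data["pith_radii"] if "pith_radii" in data else None,
            )
    except Exception:  # corrupted entry: recompute rather than crash
        logger.warning("corrupted semantic cache entry %s; recomputing", path)
        return None


# ---------------------------------------------------------------------------
# unroll scheduling
# ---------------------------------------------------------------------------

@dataclass
class UnrollRecord:
    """One (sample, ring-start, duplicate) training record."""

    sample_id: str
    ring: int       # 0 = pith boundary, r = outer edge of ring r
    duplicate: int  # 0..K-1, also the stagger offset

    def step(self, epoch: int, k: int) -> int:
        return (epoch - self.duplicate) % k

    def key(self, epoch_parity: int) -> str:
        return f"{self.sample_id}_r{self.ring}_d{self.duplicate}_{epoch_parity}"


class UnrollState:
    """File-backed boundary state for every unroll record.

    At step 0 a record's boundary resets to its ground-truth ring
    start; otherwise the boundary predicted in the previous epoch is
    read back.  Files are keyed by epoch parity so generation e and
    e+1 never collide.
    """

    def __init__(self, records, gt_starts, state_dir, k: int):
        self.records = list(records)
        self.gt_starts = gt_starts  # (sample_id, ring) -> BoundaryPolyline
        self.dir = Path(state_dir)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.k = k

    def boundary_for(self, record: UnrollRecord, epoch: int) -> BoundaryPolyline:
        # step 0, or the warm-up epochs before this duplicate's staggered
        # start: begin from the ground-truth ring
        if record.step(epoch, self.k) == 0 or epoch < record.duplicate:
            return self.gt_starts[(record.sample_id, record.ring)]
        path = self.dir / (record.key((epoch - 1) % 2) + ".json")
        if not path.exists():
            logger.warning("missing boundary file %s; resetting to start", path)
            return self.gt_starts[(record.sample_id, record.ring)]
        data = json.loads(path.read_text())
        return BoundaryPolyline(
            np.array(data["center"]), np.array(data["radii"])
        )

    def save_boundary(self, record: UnrollRecord, epoch: int,
                      boundary: BoundaryPolyline):
        path = self.dir / (record.key(epoch % 2) + ".json")
        path.write_text(json.dumps({
            "center": list(map(float, boundary.center)),
            "radii": list(map(float, boundary.radii)),
        }))


def build_records(sample_rings, k: int):
    """All (sample, ring-start, duplicate) records, K duplicates each.

    ``sample_rings``: {sample_id: n_rings}.  Ring starts are 0 (pith
    boundary) through n_rings - 1; the outermost ring's outer edge is
    excluded because it never has a next-ring target.
    """
    records = []
    for sample_id, n_rings in sample_rings.items():
        for ring in range(0, n_rings):
            for dup in range(k):
                records.append(UnrollRecord(sample_id, ring, dup))
    return records


def naive_schedule(sample_rings, k: int, epochs: int):
    """(sample, ring, step) multiset of the naive K-inner-loop scheme.

    Reference for schedule-equivalence checks: per epoch, each start
    runs steps 0..K-1 in an inner loop, K duplicates worth of work.
    """
    out = []
    for _ in range(epochs):
        for sample_id, n_rings in sample_rings.items():
            for ring in range(0, n_rings):
                for step in range(k):
                    out.append((sample_id, ring, step))
    return out


def unrolled_schedule(records, k: int, epochs: int):
    """(sample, ring, step) multiset processed by iterative unrolling."""
    out = []
    for epoch in range(epochs):
        for rec in records:
            out.append((rec.sample_id, rec.ring, rec.step(epoch, k)))
    return out


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def unrolled_epoch(state: UnrollState, epoch, model, opt, caches, gt_masks,
                   config: RunConfig, rng):
    """One epoch of iterative-unrolling training.

    For each record (shuffled): load its boundary, build the polar
    image, compute ground-truth radial targets, run one forward pass,
    accumulate gradients (optimizer steps every ``accumulation``
    records), and save the predicted next boundary for the next epoch.
    Records whose targets are absent are carried forward unchanged and
    excluded from the loss.
    """
    order = rng.permutation(len(state.records))
    total_loss, n_loss, since_step = 0.0, 0, 0
    opt.zero_grad()
    for idx in order:
        rec = state.records[idx]
        cache = caches[rec.sample_id]
        gt_mask = gt_masks[rec.sample_id]
        boundary = state.boundary_for(rec, epoch)

        m_next = adaptive_angular_resolution(boundary)
        if config.max_angular is not None:
            m_next = min(m_next, config.max_angular)
        p = estimate_ring_width(
            boundary, cache.boundary_prob, cache.background_prob,
            factor=config.ring_width_factor,
            percentile=config.ring_width_percentile,
            blank_px=config.ring_width_blank_px,
            hit_fraction=config.ring_width_hit_fraction,
            band_halfwidth_px=(config.boundary_width_px - 1) / 2,
        )
        if p is None:
            state.save_boundary(rec, epoch, boundary)
            continue
        grid, resampled = build_polar_grid(boundary, p, config.polar_n, m_next)
        target = radial_targets(
            resampled, gt_mask, grid, p, factor=config.downscale,
            absent_fraction=config.absent_column_fraction,
        )
        if target is None:
            state.save_boundary(rec, epoch, boundary)
            continue
        d_rows, valid = target
        polar = interpolate_polar(
            cache.image_ds, cache.background_logit, cache.boundary_logit,
            grid, resampled, p,
        )
        delta, b = model(polar.data)
        target_norm = normalize_target(d_rows, config.polar_n)
        if b is None:
            loss = l1_loss(delta, target_norm, mask=valid,
                           reduction=config.loss_reduction)
        else:
            loss = laplace_nll_loss(delta, b, target_norm, mask=valid,
                                    reduction=config.loss_reduction)
        loss.backward()
        total_loss += float(loss.data) / max(int(valid.sum()), 1)
        n_loss += 1
        since_step += 1
        if since_step == config.accumulation:
            opt.step()
            opt.zero_grad()
            since_step = 0

        d_px = np.maximum(
            (delta.data.astype(float) + 1.0) * p / 2.0, 0.0
        )
        next_boundary = BoundaryPolyline(
            resampled.center.copy(), resampled.radii + d_px
        )
        state.save_boundary(rec, epoch, next_boundary)
    if since_step:
        opt.step()
        opt.zero_grad()
    return total_loss / max(n_loss, 1)


def train_regression(samples, seg_model, config: RunConfig = None, rng=None,
                     work_dir=None, epochs=None, with_uncertainty=None,
                     caches=None, log=None):
    """Train the radial regression model with iterative unrolling.

    ``samples``: list of (id, RingImage, InstanceMask).  The semantic
    model's predictions are cached to disk once; every ground-truth
    ring boundary of every image is a start, duplicated K times with
    staggered offsets.  Returns the trained RegressionNet.
    """
    import tempfile

    config = config or RunConfig()
    rng = rng or np.random.default_rng(config.seed)
    epochs = epochs or config.reg_epochs
    if with_uncertainty is None:
        with_uncertainty = config.with_uncertainty
    work_dir = Path(work_dir or tempfile.mkdtemp(prefix="ringseg_unroll_"))

    if caches is None:
        caches = precompute_semantic(
            [(s, im, mk) for s, im, mk in samples], seg_model,
            work_dir / "semantic_cache", config,
        )
    gt_masks = {s: mk for s, _, mk in samples}

    # ground-truth ring starts in downscaled coordinates
    gt_starts = {}
    sample_rings = {}
    f = config.downscale
    for sample_id, _, mask in samples:
        n = mask.n_rings
        sample_rings[sample_id] = n
        angular = max(16, int(round(2 * np.pi * 20)))
        pith = pith_boundary(mask, angular)
        boundaries = ground_truth_boundaries(mask, angular, center=pith.center)
        gt_starts[(sample_id, 0)] = pith.to_ds(f)
        for r in range(1, n):
            gt_starts[(sample_id, r)] = boundaries[r - 1].to_ds(f)

    records = build_records(sample_rings, config.unroll_k)
    state = UnrollState(records, gt_starts, work_dir / "boundaries",
                        config.unroll_k)
    model = RegressionNet(
        base=config.reg_channels, aspp=config.aspp_channels,
        with_uncertainty=with_uncertainty, b_floor=config.b_floor, rng=rng,
    )
    opt = nn.Adam(model.parameters(), lr=config.lr_start)
    losses = []
    for epoch in range(epochs):
        opt.lr = nn.cosine_lr(epoch, epochs, config.lr_start, config.lr_end)
        loss = unrolled_epoch(state, epoch, model, opt, caches, gt_masks,
                              config, rng)
        losses.append(loss)
        if log is not None:
            log({"epoch": epoch, "loss": loss, "lr": opt.lr})
    model.loss_history = losses
    return model
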