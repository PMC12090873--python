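"""The pith-to-bark iterative prediction loop and mask rendering.

Each iteration: (1) set the angular resolution M from the current
boundary's mean radius; (2) estimate the next ring width P from the
boundary evidence — an absent estimate is the stopping signal; (3)
build and interpolate the polar image; (4) regress per-angle distances
to the next boundary; (5) advance the boundary by the (non-negative)
distances.  A hard iteration cap guarantees termination.  Finally the
boundary polygons are upscaled and rasterized outside-in into a
full-resolution instance mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import polygon

from .config import RunConfig
from .io import InstanceMask, RingImage
from .polar import (
    BoundaryPolyline,
    adaptive_angular_resolution,
    build_polar_grid,
    ds_to_full,
    estimate_ring_width,
    interpolate_polar,
)
from .radial_reg import (
    RadialPrediction,
    RegressionNet,
    normalize_target,
    regression_forward,
)
from .semantic import SemanticOutput, downscale_image, normalize_image, semantic_forward, extract_pith

__all__ = [
    "RingPrediction",
    "predict",
    "render_masks",
    "clamp_nonnegative",
    "ModelRegressor",
    "GroundTruthRegressor",
    "ArgmaxBaselineRegressor",
]


@dataclass
class RingPrediction:
    """Ordered boundaries (pith first), optional sigmas, full-res mask."""

    boundaries: list            # BoundaryPolyline, downscaled coords
    sigmas: list                # per-boundary (M,) sigma arrays or None
    mask: InstanceMask

    @property
    def n_rings(self) -> int:
        return len(self.boundaries) - 1


def clamp_nonnegative(d_px):
    """Predicted distances may not move the boundary inward: max(d, 0)."""
    return np.maximum(np.asarray(d_px, dtype=float), 0.0)


class ModelRegressor:
    """Adapter: trained RegressionNet -> regressor callable."""

    def __init__(self, model: RegressionNet, config: RunConfig = None):
        self.model = model
        self.config = config or RunConfig()

    def __call__(self, polar) -> RadialPrediction:
        return regression_forward(polar, self.model, self.config)


class GroundTruthRegressor:
    """Oracle regressor returning exact normalized ground-truth distances.

    Isolates the iterative geometry from learning in tests: distances
    are measured on the ground-truth instance mask along the polar
    grid's rays.
    """

    def __init__(self, gt_mask: InstanceMask, factor: int = 4):
        self.gt_mask = gt_mask
        self.factor = factor

    def __call__(self, polar) -> RadialPrediction:
        from .unrolled import radial_targets

        grid = _grid_from_polar(polar)
        result = radial_targets(polar.origin_boundary, self.gt_mask, grid,
                                polar.p, factor=self.factor)
        if result is None:
            d = np.zeros(polar.m)  # no next ring: do not advance
        else:
            d, valid = result
            if valid.any():
                d = np.where(valid, d, np.median(d[valid]))
            else:
                d = np.zeros(polar.m)
        return RadialPrediction(
            delta=normalize_target(d, polar.n), p=polar.p, n=polar.n
        )


class ArgmaxBaselineRegressor:
    """Naive per-column argmax on the polar boundary-logit channel.

    The strongest boundary response along each ray is taken as the
    next boundary — the ambiguity the regression formulation is meant
    to remove (it may jump across rings).  Rows within the blanking
    distance of the current boundary are excluded.
    """

    def __init__(self, blank_px: float = 2.0):
        self.blank_px = blank_px

    def __call__(self, polar) -> RadialPrediction:
        boundary_logit = polar.data[4]
        blank_rows = min(
            polar.n - 1, int(np.ceil(self.blank_px / polar.ray_step))
        )
        d = blank_rows + boundary_logit[blank_rows:].argmax(axis=0)
        return RadialPrediction(
            delta=normalize_target(d.astype(float), polar.n),
            p=polar.p, n=polar.n,
        )


def _grid_from_polar(polar):
    """Reconstruct the sample-coordinate grid of a PolarImage."""
    b = polar.origin_boundary
    dirs = b.directions()
    r = b.radii[None, :] + polar.ray_step * np.arange(polar.n)[:, None]
    return b.center[:, None, None] + dirs[:, None, :] * r[None, :, :]


def render_masks(boundaries, h: int, w: int, upscale_factor: int = 4,
                 pith_label: int = 0) -> InstanceMask:
    """Rasterize boundary polygons outside-in into nested annuli.

    Continuous polygon coordinates are multiplied up to full
    resolution, then filled polygons are drawn from the outermost
    boundary inward, each overwriting the previous draw's interior;
    the region outside the outermost boundary stays 0 and the interior
    of the first (pith) boundary receives ``pith_label``.
    """
    canvas = np.zeros((h, w), dtype=np.int32)
    for i in range(len(boundaries) - 1, -1, -1):
        pts = ds_to_full(boundaries[i].points, upscale_factor)
        rr, cc = polygon(pts[0], pts[1], shape=(h, w))
        canvas[rr, cc] = i if i > 0 else pith_label
    return InstanceMask(labels=canvas)


def predict(image: RingImage, seg_model, regressor, config: RunConfig = None,
            pith_override: BoundaryPolyline = None,
            semantic: SemanticOutput = None) -> RingPrediction:
    """Run the full iterative ring segmentation on one image.

    ``regressor`` is any callable PolarImage -> RadialPrediction (a
    trained net via ModelRegressor, the ground-truth oracle, or the
    argmax baseline).  ``pith_override`` supplies a user pith boundary
    (downscaled coordinates) when the semantic model cannot find one,
    e.g. on species unseen in training.
    """
    config = config or RunConfig()
    if semantic is None:
        semantic = semantic_forward(image, seg_model, config)
    boundary_prob = semantic.prob("boundary")
    background_prob = semantic.prob("background")

    if pith_override is not None:
        current = pith_override
    else:
        _, current = extract_pith(semantic, config.pith_threshold)

    ds = downscale_image(image.pixels, config.downscale)
    image_ds = normalize_image(ds)

    boundaries = [current]
    sigmas = [None]
    for _ in range(config.max_iterations):
        m_next = adaptive_angular_resolution(current)
        if config.max_angular is not None:
            m_next = min(m_next, config.max_angular)
        p = estimate_ring_width(
            current, boundary_prob, background_prob,
            factor=config.ring_width_factor,
            percentile=config.ring_width_percentile,
            blank_px=config.ring_width_blank_px,
            hit_fraction=config.ring_width_hit_fraction,
            band_halfwidth_px=(config.boundary_width_px - 1) / 2,
        )
        if p is None:  # missing ring width estimate: bark/xylem edge reached
            break
        grid, resampled = build_polar_grid(current, p, config.polar_n, m_next)
        polar = interpolate_polar(
            image_ds, semantic.logit("background"), semantic.logit("boundary"),
            grid, resampled, p,
        )
        pred = regressor(polar)
        d_px = clamp_nonnegative(pred.d_px)
        if d_px.mean() < config.min_advance_px:
            break  # degenerate step: boundary no longer moves outward
        current = BoundaryPolyline(resampled.center.copy(),
                                   resampled.radii + d_px)
        boundaries.append(current)
        sigmas.append(pred.sigma_px)

    h, w = image.shape
    mask = render_masks(boundaries, h, w, config.downscale, config.pith_label)
    return RingPrediction(boundaries=boundaries, sigmas=sigmas, mask=mask)
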