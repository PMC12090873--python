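"""Synthetic cross-section images with known ring instance masks.

The generator emulates the statistical structure of microscopic shrub
thin sections that the method assumes: concentric rings around a pith,
smoothly varying per-angle ring widths (low-order Fourier
perturbations), wedging rings that pinch to zero width over a
contiguous angular arc, dark 1-3 px boundary bands between rings, a
visually distinct pith that may optionally be rendered background-like
(emulating piths torn off during thin-sectioning), and background
outside the xylem.  It is *not* photorealistic: no cell lumina or
species-specific anatomy are rendered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .io import InstanceMask, RingImage
from .polar import BoundaryPolyline, ray_march_outer

__all__ = [
    "SyntheticSpec",
    "generate_sample",
    "ground_truth_boundaries",
    "pith_boundary",
]

_WOOD = np.array([196.0, 168.0, 128.0])
_PITH = np.array([120.0, 82.0, 60.0])
_BACKGROUND = np.array([238.0, 238.0, 236.0])
_BOUNDARY = np.array([92.0, 64.0, 46.0])


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic cross-section.

    Defaults describe a mid-size shrub section: a 256 px square image,
    5 rings of mean width 18 px around a 16 px pith, 15% relative
    per-angle width variation, and a 25% chance per ring (innermost
    excluded) of wedging out over an arc.
    """

    image_size: int = 256
    n_rings: int = 5
    mean_ring_width: float = 18.0
    width_jitter: float = 0.15
    wedging_prob: float = 0.25
    pith_radius: float = 16.0
    pith_damage_prob: float = 0.0
    texture_noise_sd: float = 6.0
    boundary_band_px: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_rings < 1:
            raise ValueError("n_rings must be >= 1")
        if self.mean_ring_width < 2:
            raise ValueError("mean_ring_width must be >= 2 px")
        for name in ("wedging_prob", "pith_damage_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        extent = self.pith_radius + self.n_rings * self.mean_ring_width
        if extent > self.image_size / 2:
            raise ValueError(
                f"total ring extent {extent:.0f} px exceeds half the image "
                f"size ({self.image_size / 2:.0f} px)"
            )


def _smooth_profile(rng, n_angles, sd, max_order=3):
    """Zero-mean smooth periodic perturbation with std ~ sd."""
    th = 2 * np.pi * np.arange(n_angles) / n_angles
    out = np.zeros(n_angles)
    for j in range(1, max_order + 1):
        amp = rng.normal(0.0, 1.0 / max_order**0.5)
        phase = rng.uniform(0, 2 * np.pi)
        out += amp * np.cos(j * th + phase)
    # normalize to unit std then scale (amp draw already ~unit, keep exact)
    s = out.std()
    if s > 1e-9:
        out = out / s
    return sd * out


def _ring_profiles(spec: SyntheticSpec, rng, n_angles=720):
    """Radial boundary profiles r_0..r_n (pith edge to outermost edge)."""
    th = 2 * np.pi * np.arange(n_angles) / n_angles
    r0 = spec.pith_radius * (
        1.0 + 0.5 * _smooth_profile(rng, n_angles, spec.width_jitter)
    )
    profiles = [np.maximum(r0, 2.0)]
    for k in range(spec.n_rings):
        width = spec.mean_ring_width * (
            1.0 + _smooth_profile(rng, n_angles, spec.width_jitter)
        )
        width = np.maximum(width, 0.15 * spec.mean_ring_width)
        # wedging: clamp the width to zero where a smooth dip crosses it
        # (the innermost ring is kept intact so the pith stays enclosed)
        if k > 0 and rng.uniform() < spec.wedging_prob:
            arc_center = rng.uniform(0, 2 * np.pi)
            arc_half = rng.uniform(0.4, 1.0)
            depth = rng.uniform(1.2, 1.8) * spec.mean_ring_width
            u = np.angle(np.exp(1j * (th - arc_center))) / arc_half
            window = np.where(np.abs(u) < 1, np.cos(np.abs(u) * np.pi / 2), 0.0)
            width = width - depth * window
        width = np.maximum(width, 0.0)
        profiles.append(profiles[-1] + width)
    profiles = np.stack(profiles)  # (n_rings+1, n_angles)

    limit = spec.image_size / 2 - 2
    peak = profiles[-1].max()
    if peak > limit:  # jitter pushed the outer edge too far: shrink widths
        widths = np.diff(profiles, axis=0) * (limit - profiles[0]) / (
            peak - profiles[0].min()
        )
        profiles = np.concatenate(
            [profiles[:1], profiles[:1] + np.cumsum(widths, axis=0)]
        )
        profiles = np.minimum(profiles, limit)
    return profiles


def generate_sample(spec: SyntheticSpec):
    """Generate one (RingImage, InstanceMask) pair.

    Ring k occupies the closed annular band between the smoothed radial
    profiles r_{k-1}(theta) and r_k(theta); label 0 is background
    outside the xylem (and the pith interior); labels 1..n_rings are
    ordered pith to bark.  Identical spec (including seed) gives
    bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    center = size / 2 + rng.uniform(-4, 4, size=2)
    profiles = _ring_profiles(spec, rng)
    n_angles = profiles.shape[1]

    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    drow, dcol = rr - center[0], cc - center[1]
    rad = np.hypot(drow, dcol)
    theta = np.mod(np.arctan2(-drow, dcol), 2 * np.pi)

    th_grid = 2 * np.pi * np.arange(n_angles) / n_angles
    prof_at_pixel = np.stack(
        [np.interp(theta, th_grid, p, period=2 * np.pi) for p in profiles]
    )  # (n+1, H, W)
    count = (rad[None] >= prof_at_pixel).sum(axis=0)
    labels = np.where((count >= 1) & (count <= spec.n_rings), count, 0)
    labels = labels.astype(np.int32)

    # ---- render the RGB image -----------------------------------------
    img = np.empty((size, size, 3))
    img[:] = _BACKGROUND
    xylem = (count >= 1) & (count <= spec.n_rings)
    ring_tints = rng.uniform(-12, 12, size=(spec.n_rings + 2, 3))
    for k in range(1, spec.n_rings + 1):
        img[labels == k] = _WOOD + ring_tints[k]
    pith_region = count == 0
    damaged = rng.uniform() < spec.pith_damage_prob
    img[pith_region] = _BACKGROUND if damaged else _PITH

    # dark boundary bands at each ring's outer edge (and the pith edge)
    band = spec.boundary_band_px / 2.0
    for k in range(0, spec.n_rings + 1):
        on_edge = np.abs(rad - prof_at_pixel[k]) <= band
        if k > 0:  # skip zero-width wedge arcs: no physical edge there
            has_width = np.interp(
                theta, th_grid, (profiles[k] - profiles[k - 1]) > 1e-6,
                period=2 * np.pi,
            ) > 0.5
            on_edge &= has_width
        img[on_edge] = _BOUNDARY

    img += rng.normal(0.0, spec.texture_noise_sd, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)

    image = RingImage(pixels=img, id=f"synthetic_seed{spec.seed}")
    return image, InstanceMask(labels=labels)


def pith_boundary(mask: InstanceMask, angular_points: int,
                  center=None) -> BoundaryPolyline:
    """The inner boundary of ring 1 (outer edge of the pith region)."""
    fg = mask.labels > 0
    interior = ndi.binary_fill_holes(fg) & ~fg
    if not interior.any():
        raise ValueError("mask has no enclosed pith region")
    if center is None:
        rows, cols = np.nonzero(interior)
        center = np.array([rows.mean(), cols.mean()])
    angles = 2 * np.pi * np.arange(angular_points) / angular_points
    r_max = float(np.hypot(*mask.shape))
    radii = ray_march_outer(interior, center, angles, r_max)
    radii = np.where(np.isnan(radii), np.nanmedian(radii), radii)
    return BoundaryPolyline(np.asarray(center, dtype=float), radii)


def ground_truth_boundaries(mask: InstanceMask, angular_points: int,
                            center=None):
    """Outer boundary polyline of each ring, sampled at equal angles.

    The outer boundary of ring k is taken as the outer edge of the
    union of rings 1..k along each ray, so on arcs where ring k wedges
    to zero width the boundary coincides with the inner boundary.
    Usable both as training targets and as the oracle regressor.
    """
    n = mask.n_rings
    if n < 1:
        raise ValueError("mask contains no rings")
    if center is None:
        fg = mask.labels > 0
        interior = ndi.binary_fill_holes(fg) & ~fg
        region = interior if interior.any() else mask.labels == 1
        rows, cols = np.nonzero(region)
        center = np.array([rows.mean(), cols.mean()])
    center = np.asarray(center, dtype=float)
    angles = 2 * np.pi * np.arange(angular_points) / angular_points
    r_max = float(np.hypot(*mask.shape))
    boundaries = []
    prev = None
    for k in range(1, n + 1):
        member = (mask.labels >= 1) & (mask.labels <= k)
        radii = ray_march_outer(member, center, angles, r_max)
        if np.isnan(radii).any():
            fallback = prev if prev is not None else np.nanmedian(radii)
            radii = np.where(np.isnan(radii), fallback, radii)
        if prev is not None:
            radii = np.maximum(radii, prev)  # nestedness against sampling noise
        boundaries.append(BoundaryPolyline(center.copy(), radii))
        prev = radii
    return boundaries
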