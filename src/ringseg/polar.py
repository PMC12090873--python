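"""Polar geometry of the iterative scheme.

Coordinate conventions (shared by every module):

* pixel coordinates are ``(row, col)``, 0-based, pixel centers at
  integer coordinates;
* angles are measured from image-east (increasing column), proceeding
  counter-clockwise on screen, i.e. ``row = cr - r*sin(theta)``,
  ``col = cc + r*cos(theta)``;
* boundaries are star-shaped around a shared center and stored as radii
  sampled at M equally spaced angles;
* the downscaled grid relates to the full-resolution grid through
  ``full = f*ds + (f-1)/2`` (area-average block centers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "BoundaryPolyline",
    "ray_march_outer",
    "PolarImage",
    "ds_to_full",
    "full_to_ds",
    "adaptive_angular_resolution",
    "estimate_ring_width",
    "build_polar_grid",
    "interpolate_polar",
]


def ds_to_full(coords, factor):
    """Map downscaled pixel coordinates to full-resolution coordinates."""
    return np.asarray(coords, dtype=float) * factor + (factor - 1) / 2.0


def full_to_ds(coords, factor):
    return (np.asarray(coords, dtype=float) - (factor - 1) / 2.0) / factor


@dataclass
class BoundaryPolyline:
    """A closed ring boundary: a center plus M radii at equal angles.

    ``points`` gives the boundary positions as a (2, M) array of
    (row, col) coordinates ordered by angle; the curve is closed and
    angularly monotone by construction.
    """

    center: np.ndarray  # (2,) row, col
    radii: np.ndarray   # (M,)

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.radii.ndim != 1 or self.radii.size < 4:
            raise ValueError("boundary needs at least 4 angular samples")

    @property
    def m(self) -> int:
        return self.radii.size

    @property
    def angles(self) -> np.ndarray:
        return 2 * np.pi * np.arange(self.m) / self.m

    @property
    def mean_radius(self) -> float:
        return float(self.radii.mean())

    def directions(self) -> np.ndarray:
        """(2, M) unit ray directions (row, col) at each angle."""
        th = self.angles
        return np.stack([-np.sin(th), np.cos(th)])

    @property
    def points(self) -> np.ndarray:
        return self.center[:, None] + self.radii[None, :] * self.directions()

    def resample(self, m_new: int) -> "BoundaryPolyline":
        """Resample to ``m_new`` equal angles (periodic linear interpolation)."""
        if m_new == self.m:
            return BoundaryPolyline(self.center.copy(), self.radii.copy())
        new_angles = 2 * np.pi * np.arange(m_new) / m_new
        radii = np.interp(new_angles, self.angles, self.radii, period=2 * np.pi)
        return BoundaryPolyline(self.center.copy(), radii)

    def to_full(self, factor: int) -> "BoundaryPolyline":
        return BoundaryPolyline(ds_to_full(self.center, factor), self.radii * factor)

    def to_ds(self, factor: int) -> "BoundaryPolyline":
        return BoundaryPolyline(full_to_ds(self.center, factor), self.radii / factor)


@dataclass
class PolarImage:
    """6xNxM resampling of the scene outward from the current boundary.

    Channels: 3 image channels, background logit, boundary logit, and
    the min-max-normalized distance to the center.  Row 0 lies exactly
    on ``origin_boundary``; consecutive rows step ``ray_step = P/N``
    pixels outward along each ray.
    """

    data: np.ndarray            # (6, N, M) float32
    p: float                    # ring-width estimate P (downscaled px)
    origin_boundary: BoundaryPolyline
    center: np.ndarray = field(default=None)

    @property
    def n(self) -> int:
        return self.data.shape[1]

    @property
    def m(self) -> int:
        return self.data.shape[2]

    @property
    def ray_step(self) -> float:
        return self.p / self.n


def ray_march_outer(member: np.ndarray, center, angles, r_max, step=0.5):
    """Outermost radius at which ``member`` is true along each ray.

    Nearest-neighbour sampling at ``step``-pixel radial increments;
    rays with no member pixel return NaN.
    """
    radii_samples = np.arange(0, r_max + step, step)
    rows = center[0] - np.sin(angles)[:, None] * radii_samples[None, :]
    cols = center[1] + np.cos(angles)[:, None] * radii_samples[None, :]
    r = np.clip(np.round(rows).astype(int), 0, member.shape[0] - 1)
    c = np.clip(np.round(cols).astype(int), 0, member.shape[1] - 1)
    inside = (
        (rows >= -0.5) & (rows < member.shape[0] - 0.5)
        & (cols >= -0.5) & (cols < member.shape[1] - 0.5)
    )
    hit = member[r, c] & inside
    any_hit = hit.any(axis=1)
    last = hit.shape[1] - 1 - hit[:, ::-1].argmax(axis=1)
    # the true edge lies between the last member sample and the next one
    return np.where(any_hit, radii_samples[last] + step / 2, np.nan)


def adaptive_angular_resolution(boundary: BoundaryPolyline) -> int:
    """M for the next ring: round(2*pi * mean boundary radius), >= 8.

    Keeps the arc spacing between consecutive boundary points near one
    pixel at every radius.
    """
    r = boundary.mean_radius
    if r <= 0:
        raise ValueError("degenerate boundary: all points at the center")
    return max(8, int(round(2 * np.pi * r)))


def _sample_nearest(mask: np.ndarray, rows: np.ndarray, cols: np.ndarray, fill=0):
    """Nearest-neighbour sampling with out-of-bounds fill."""
    r = np.round(rows).astype(int)
    c = np.round(cols).astype(int)
    inside = (r >= 0) & (r < mask.shape[0]) & (c >= 0) & (c < mask.shape[1])
    out = np.full(rows.shape, fill, dtype=mask.dtype)
    out[inside] = mask[r[inside], c[inside]]
    return out, inside


def estimate_ring_width(
    boundary: BoundaryPolyline,
    boundary_prob: np.ndarray,
    background_prob: np.ndarray,
    factor: float = 1.5,
    percentile: float = 95.0,
    blank_px: float = 2.0,
    hit_fraction: float = 0.2,
    step_px: float = 1.0,
    band_halfwidth_px: float = 0.0,
):
    """Outlier-robust estimate P of the next ring's width, or None.

    From each boundary point, march radially outward (after a small
    blanking distance that skips the current boundary's own mass) until
    a binarized boundary pixel is hit; a ray is abandoned when it
    reaches binarized background or leaves the image.  P is ``factor``
    times the ``percentile``-th percentile of the hit distances.  When
    fewer than ``hit_fraction`` of the rays hit anything, the ring
    width estimate is *absent* — the iterative process's stopping
    signal — and None is returned.
    """
    h, w = boundary_prob.shape
    max_dist = float(np.hypot(h, w))
    n_steps = int(np.ceil((max_dist - blank_px) / step_px))
    dists = blank_px + step_px * np.arange(n_steps)  # (S,)

    dirs = boundary.directions()  # (2, M)
    radii = boundary.radii
    rows = boundary.center[0] + dirs[0][:, None] * (radii[:, None] + dists[None, :])
    cols = boundary.center[1] + dirs[1][:, None] * (radii[:, None] + dists[None, :])

    bnd, inside = _sample_nearest(boundary_prob >= 0.5, rows, cols, fill=False)
    bg, _ = _sample_nearest(background_prob >= 0.5, rows, cols, fill=False)
    stop = bg | ~inside

    # first hit / first stop per ray
    hit_any = bnd.any(axis=1)
    first_hit = np.where(hit_any, bnd.argmax(axis=1), n_steps)
    stop_any = stop.any(axis=1)
    first_stop = np.where(stop_any, stop.argmax(axis=1), n_steps)

    valid = hit_any & (first_hit < first_stop)
    if valid.mean() < hit_fraction:
        return None
    # the first hit lands on the inner lip of the (dilated) boundary band;
    # compensate by its half-width so the distance refers to the band center
    hit_dists = dists[first_hit[valid]] + band_halfwidth_px
    return float(factor * np.percentile(hit_dists, percentile))


def build_polar_grid(boundary: BoundaryPolyline, p: float, n: int, m_next: int):
    """Sample coordinates fanning out radially from the boundary.

    Returns ``(grid, resampled)`` where ``grid`` is a (2, N, M_next)
    array of (row, col) coordinates: column m's ray starts on the
    boundary (resampled to M_next angles) and proceeds outward along
    the direction from the shared center through that point, with step
    ``P/N``.  Row 0 equals the resampled boundary points.
    """
    if p <= 0:
        raise ValueError("ring width estimate P must be positive")
    resampled = boundary.resample(m_next)
    step = p / n
    dirs = resampled.directions()  # (2, M)
    r = resampled.radii[None, :] + step * np.arange(n)[:, None]  # (N, M)
    grid = resampled.center[:, None, None] + dirs[:, None, :] * r[None, :, :]
    return grid, resampled


def interpolate_polar(
    image_ds: np.ndarray,
    background_logit: np.ndarray,
    boundary_logit: np.ndarray,
    grid: np.ndarray,
    resampled: BoundaryPolyline,
    p: float,
) -> PolarImage:
    """Bilinear interpolation of image + raw logits onto the polar grid.

    ``image_ds`` is (3, h, w); logits are interpolated pre-activation.
    The 6th channel is the per-sample distance to the center, min-max
    normalized to [0, 1] within this polar image.  Out-of-bounds
    samples take the fill value 0.
    """
    n, m = grid.shape[1], grid.shape[2]
    channels = np.concatenate(
        [np.asarray(image_ds, dtype=np.float32),
         background_logit[None].astype(np.float32),
         boundary_logit[None].astype(np.float32)]
    )
    coords = grid.reshape(2, -1)
    out = np.empty((6, n, m), dtype=np.float32)
    for i in range(5):
        out[i] = map_coordinates(
            channels[i], coords, order=1, mode="constant", cval=0.0
        ).reshape(n, m)

    step = p / n
    dist = resampled.radii[None, :] + step * np.arange(n)[:, None]
    lo, hi = dist.min(), dist.max()
    out[5] = (dist - lo) / max(hi - lo, 1e-9)
    return PolarImage(data=out, p=float(p), origin_boundary=resampled,
                      center=resampled.center.copy())
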