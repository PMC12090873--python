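"""Polar geometry: adaptive resolution, ring-width estimate, grid,
interpolation, and the radial round-trip property."""

import numpy as np
import pytest

from ringseg.polar import (
    BoundaryPolyline,
    adaptive_angular_resolution,
    build_polar_grid,
    estimate_ring_width,
    interpolate_polar,
)


def circle(radius, m=64, center=(50.0, 50.0)):
    return BoundaryPolyline(np.array(center), np.full(m, float(radius)))


@pytest.mark.parametrize("radius,expected", [(10, 63), (100, 628)])
def test_adaptive_resolution_circle(radius, expected):
    assert adaptive_angular_resolution(circle(radius)) == expected


def test_adaptive_resolution_uses_mean_radius():
    radii = np.empty(64)
    radii[::2], radii[1::2] = 10.0, 20.0
    b = BoundaryPolyline(np.array([0.0, 0.0]), radii)
    assert adaptive_angular_resolution(b) == round(2 * np.pi * 15)  # 94


def test_adaptive_resolution_clamps_and_rejects():
    assert adaptive_angular_resolution(circle(0.5)) == 8
    with pytest.raises(ValueError):
        adaptive_angular_resolution(circle(0.0))


def _maps_with_ring(shape, center, radius, band=1.0):
    rr, cc = np.meshgrid(*map(np.arange, shape), indexing="ij")
    rad = np.hypot(rr - center[0], cc - center[1])
    boundary = (np.abs(rad - radius) <= band).astype(float)
    return boundary, np.zeros(shape)


def test_ring_width_all_rays_hit_at_ten():
    center = (100.0, 100.0)
    boundary_prob, bg = _maps_with_ring((200, 200), center, 30.0, band=0.6)
    p = estimate_ring_width(circle(20, 128, center), boundary_prob, bg)
    assert p == pytest.approx(15.0, abs=1.5)


def test_ring_width_percentile_brute_force():
    """10% of rays see a far boundary: P follows the constructed multiset
    (the 95th percentile lands on the far distance, so the estimate makes
    the polar window long enough to contain the next boundary)."""
    m = 100
    center = (128.0, 128.0)
    b = circle(20, m, center)
    rr, cc = np.meshgrid(np.arange(256), np.arange(256), indexing="ij")
    rad = np.hypot(rr - center[0], cc - center[1])
    th = np.mod(np.arctan2(-(rr - center[0]), cc - center[1]), 2 * np.pi)
    near = (np.abs(rad - 30.0) <= 0.6) & (th < 2 * np.pi * 0.9)
    far = (np.abs(rad - 70.0) <= 0.6) & (th >= 2 * np.pi * 0.9)
    boundary_prob = (near | far).astype(float)
    p = estimate_ring_width(b, boundary_prob, np.zeros_like(boundary_prob))
    # brute-force percentile of the hit-distance multiset
    dists = np.r_[np.full(90, 10.0), np.full(10, 50.0)]
    assert p == pytest.approx(1.5 * np.percentile(dists, 95), rel=0.05)


def test_ring_width_absent_when_nothing_outside():
    boundary_prob = np.zeros((100, 100))
    bg = np.zeros((100, 100))
    assert estimate_ring_width(circle(20), boundary_prob, bg) is None


def test_ring_width_absent_when_background_blocks():
    center = (50.0, 50.0)
    boundary_prob, _ = _maps_with_ring((100, 100), center, 40.0, band=0.6)
    rr, cc = np.meshgrid(np.arange(100), np.arange(100), indexing="ij")
    bg = (np.hypot(rr - center[0], cc - center[1]) > 25).astype(float)
    assert estimate_ring_width(circle(20, 64, center), boundary_prob, bg) is None


def test_grid_row0_is_boundary_and_steps_are_radial():
    b = circle(10.0, 32, (40.0, 45.0))
    grid, resampled = build_polar_grid(b, p=16.0, n=8, m_next=48)
    assert grid.shape == (2, 8, 48)
    assert np.allclose(grid[:, 0, :], resampled.points, atol=1e-9)
    # constant-radius construction: row n sits at radius r + n*step
    rad = np.hypot(grid[0] - 40.0, grid[1] - 45.0)
    for n in range(8):
        assert np.allclose(rad[n], 10.0 + n * 2.0, atol=1e-9)


def test_grid_rays_collinear_with_center_direction():
    rng = np.random.default_rng(0)
    radii = 10 + rng.uniform(-2, 2, 32)  # off-circular boundary
    b = BoundaryPolyline(np.array([30.0, 30.0]), radii)
    grid, resampled = build_polar_grid(b, p=8.0, n=6, m_next=32)
    v = grid[:, -1, :] - grid[:, 0, :]           # ray displacement
    u = resampled.points - resampled.center[:, None]  # center direction
    cross = v[0] * u[1] - v[1] * u[0]
    assert np.abs(cross).max() < 1e-9


def test_interpolation_constant_image_and_lattice_exactness():
    image = np.full((3, 64, 64), 3.25, dtype=np.float32)
    bg = np.zeros((64, 64), np.float32)
    rng = np.random.default_rng(1)
    bnd = rng.normal(size=(64, 64)).astype(np.float32)
    b = circle(10.0, 16, (32.0, 32.0))
    grid, res = build_polar_grid(b, p=8.0, n=4, m_next=16)
    polar = interpolate_polar(image, bg, bnd, grid, res, p=8.0)
    assert np.allclose(polar.data[:3], 3.25, atol=1e-6)
    # channel 6 increases monotonically down each column and spans [0, 1]
    d6 = polar.data[5]
    assert (np.diff(d6, axis=0) > 0).all()
    assert d6.min() == 0.0 and d6.max() == 1.0
    # grid points coincident with pixel centers reproduce source values
    b2 = BoundaryPolyline(np.array([32.0, 32.0]), np.array([5.0] * 4))
    grid2, res2 = build_polar_grid(b2, p=4.0, n=4, m_next=4)
    polar2 = interpolate_polar(image, bg, bnd, grid2, res2, p=4.0)
    rows = np.round(grid2[0]).astype(int)
    cols = np.round(grid2[1]).astype(int)
    assert np.allclose(polar2.data[4], bnd[rows, cols], atol=1e-5)


def test_round_trip_gap_appears_at_expected_row():
    """A ring at constant radial gap d lands at polar row d/(P/N) +- 1."""
    center = (100.0, 100.0)
    gap, radius, p, n = 12.0, 30.0, 18.0, 64
    boundary_prob, bg = _maps_with_ring((200, 200), center,
                                        radius + gap, band=0.6)
    b = circle(radius, 128, center)
    grid, res = build_polar_grid(b, p, n, 128)
    polar = interpolate_polar(np.zeros((3, 200, 200), np.float32),
                              bg.astype(np.float32),
                              boundary_prob.astype(np.float32),
                              grid, res, p)
    hit_rows = polar.data[4].argmax(axis=0)
    expected = gap / (p / n)
    # deviation measured in pixels: +-1 px around the expected row
    assert (np.abs(hit_rows - expected).max() * (p / n)) <= 1.0


def test_arc_spacing_about_one_pixel():
    for radius in (7.0, 23.0, 117.0):
        b = circle(radius, 256)
        m = adaptive_angular_resolution(b)
        spacing = 2 * np.pi * radius / m
        assert abs(spacing - 1.0) <= 0.1


def test_resample_preserves_circle_and_interpolates_angle():
    b = circle(10.0, 64)
    r2 = b.resample(17)
    assert np.allclose(r2.radii, 10.0)
    radii = np.where(np.arange(8) % 2 == 0, 10.0, 20.0)
    b2 = BoundaryPolyline(np.array([0.0, 0.0]), radii)
    r3 = b2.resample(16)
    assert r3.radii.min() >= 10.0 and r3.radii.max() <= 20.0
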