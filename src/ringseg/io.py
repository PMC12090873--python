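"""Readers/writers for images, instance masks, boundaries and overlays.

Instance masks are stored as single-channel 16-bit PNG label images
(label 0 = background/non-xylem, labels 1..n = rings ordered pith to
bark).  On read, arbitrary integer labelings are re-indexed to this
canonical ordering by mean pixel distance to the pith centroid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi
from skimage.draw import polygon_perimeter

from .polar import BoundaryPolyline

__all__ = [
    "RingImage",
    "InstanceMask",
    "read_sample",
    "write_prediction",
    "write_uncertainty_overlay",
    "write_boundaries_json",
    "read_boundaries_json",
]


@dataclass
class RingImage:
    """An RGB cross-section image (H, W, 3) uint8 with an identifier."""

    pixels: np.ndarray
    id: str = ""
    scale: float | None = None  # pixels per micron; metadata only

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("RingImage expects an (H, W, 3) array")
        if min(self.pixels.shape[:2]) < 64:
            raise ValueError("image must be at least 64x64")
        if not np.isfinite(np.asarray(self.pixels, dtype=float)).all():
            raise ValueError("image intensities must be finite")

    @property
    def shape(self):
        return self.pixels.shape[:2]


@dataclass
class InstanceMask:
    """Per-pixel integer ring labels; {0..n_rings}, 1 innermost."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("mask labels must be integers")

    @property
    def n_rings(self) -> int:
        return int(self.labels.max())

    @property
    def shape(self):
        return self.labels.shape

    def ring(self, k: int) -> np.ndarray:
        if k < 1 or k > self.n_rings:
            raise ValueError(f"ring label {k} absent (mask has {self.n_rings})")
        return self.labels == k


def pith_centroid(labels: np.ndarray) -> np.ndarray:
    """Centroid (row, col) of the region enclosed by the innermost ring.

    Falls back to the foreground centroid when the mask has no interior
    hole (e.g. rings touching the pith were not annotated).
    """
    fg = labels > 0
    interior = ndi.binary_fill_holes(fg) & ~fg
    region = interior if interior.any() else fg
    rows, cols = np.nonzero(region)
    return np.array([rows.mean(), cols.mean()])


def canonicalize_labels(labels: np.ndarray) -> np.ndarray:
    """Re-index arbitrary integer labels to contiguous pith->bark order."""
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids != 0]
    if ids.size == 0:
        raise ValueError("mask contains no ring labels")
    center = pith_centroid(labels)
    rr, cc = np.meshgrid(
        np.arange(labels.shape[0]), np.arange(labels.shape[1]), indexing="ij"
    )
    dist = np.hypot(rr - center[0], cc - center[1])
    mean_dist = [dist[labels == i].mean() for i in ids]
    order = ids[np.argsort(mean_dist)]
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(order, start=1):
        out[labels == old] = new
    return out


def read_sample(image_path, mask_path=None):
    """Read an image (and optionally its instance mask).

    The mask is re-indexed to the canonical contiguous pith->bark
    ordering if the file uses arbitrary integers.
    """
    pixels = iio.imread(image_path)
    if pixels.ndim == 2:
        pixels = np.stack([pixels] * 3, axis=-1)
    if pixels.shape[2] == 4:
        pixels = pixels[:, :, :3]
    image = RingImage(pixels=pixels.astype(np.uint8), id=Path(image_path).stem)
    if mask_path is None:
        return image, None
    raw = iio.imread(mask_path)
    if raw.ndim != 2:
        raise ValueError("mask must be single-channel")
    if not np.issubdtype(raw.dtype, np.integer):
        raise ValueError("mask must be integer-valued")
    if raw.shape != image.shape:
        raise ValueError(
            f"mask shape {raw.shape} does not match image {image.shape}"
        )
    labels = raw.astype(np.int32)
    ids = np.unique(labels)
    nonzero = ids[ids != 0]
    if nonzero.size and not np.array_equal(
        nonzero, np.arange(1, nonzero.size + 1)
    ):
        labels = canonicalize_labels(labels)
    return image, InstanceMask(labels=labels)


def write_prediction(mask: InstanceMask, path):
    """Write an instance mask as 16-bit single-channel PNG."""
    if mask.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("label range exceeds 16-bit PNG")
    iio.imwrite(Path(path), mask.labels.astype(np.uint16))


def write_image(image: RingImage, path):
    iio.imwrite(Path(path), image.pixels)


def _draw_closed(canvas, points, color):
    rows = np.round(points[0]).astype(int)
    cols = np.round(points[1]).astype(int)
    rr, cc = polygon_perimeter(rows, cols, shape=canvas.shape[:2], clip=True)
    canvas[rr, cc] = color


def write_uncertainty_overlay(image: RingImage, boundaries, sigmas, path,
                              factor: int = 1):
    """RGB overlay: each boundary plus its +-1 sigma envelope.

    ``boundaries`` are BoundaryPolyline objects in downscaled
    coordinates; ``factor`` maps them to the image grid.  ``sigmas``
    holds per-point standard deviations in downscaled pixels (None for
    a boundary without uncertainty).  With sigma = 0 the envelope lines
    coincide with the boundary line; with no boundaries the image is
    written unchanged.
    """
    canvas = image.pixels.copy()
    for boundary, sigma in zip(boundaries, sigmas):
        b = boundary.to_full(factor) if factor != 1 else boundary
        _draw_closed(canvas, b.points, np.array([220, 40, 40], np.uint8))
        if sigma is not None:
            s = np.asarray(sigma, dtype=float) * factor
            for sign in (1.0, -1.0):
                env = BoundaryPolyline(
                    b.center.copy(), np.maximum(b.radii + sign * s, 0.5)
                )
                _draw_closed(canvas, env.points, np.array([40, 90, 220], np.uint8))
    iio.imwrite(Path(path), canvas)


def write_boundaries_json(path, center, boundaries, sigmas=None):
    """Serialize boundaries (center + per-ring radii, optional sigma)."""
    payload = {
        "center": list(np.asarray(center, dtype=float)),
        "boundaries": [list(map(float, b.radii)) for b in boundaries],
    }
    if sigmas is not None:
        payload["sigmas"] = [
            None if s is None else list(map(float, s)) for s in sigmas
        ]
    Path(path).write_text(json.dumps(payload))


def read_boundaries_json(path):
    payload = json.loads(Path(path).read_text())
    center = np.array(payload["center"], dtype=float)
    boundaries = [
        BoundaryPolyline(center.copy(), np.array(r, dtype=float))
        for r in payload["boundaries"]
    ]
    sigmas = [
        None if s is None else np.array(s, dtype=float)
        for s in payload.get("sigmas", [None] * len(boundaries))
    ]
    return center, boundaries, sigmas
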