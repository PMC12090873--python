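"""Semantic pre-segmentation: pith / background / ring / boundary.

A small encoder-decoder convolutional network with skip connections
predicts one sigmoid-activated binary mask per class on a x4-downscaled
version of the input, trained with a weighted binary dice loss.  The
pith mask initializes the iterative stage; the boundary mask provides
the evidence for the ring-width estimate; background detects the edge
of the xylem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as cc_label
from skimage.transform import resize

from . import nn
from .nn import functional as F
from .config import RunConfig
from .io import InstanceMask, RingImage
from .polar import BoundaryPolyline, adaptive_angular_resolution, ray_march_outer

__all__ = [
    "SemanticOutput",
    "SegNet",
    "dice_loss",
    "seg_total_loss",
    "derive_semantic_targets",
    "semantic_forward",
    "extract_pith",
    "PithNotFoundError",
    "downscale_image",
    "normalize_image",
    "train_segmentation",
]

# standard natural-image channel statistics (0..1 scale)
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


class PithNotFoundError(RuntimeError):
    """No pith pixel above threshold; caller may supply a pith override."""


@dataclass
class SemanticOutput:
    """Pre-activation logits (4, h, w): pith, background, ring, boundary."""

    logits: np.ndarray

    CLASSES = ("pith", "background", "ring", "boundary")

    @property
    def probabilities(self) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.logits))

    def prob(self, name: str) -> np.ndarray:
        return self.probabilities[self.CLASSES.index(name)]

    def logit(self, name: str) -> np.ndarray:
        return self.logits[self.CLASSES.index(name)]


def downscale_image(pixels: np.ndarray, factor: int) -> np.ndarray:
    """Anti-aliased area downscaling to (H//f, W//f), float in [0, 1]."""
    h, w = pixels.shape[:2]
    out = resize(
        pixels.astype(np.float32) / 255.0,
        (h // factor, w // factor),
        anti_aliasing=True,
        preserve_range=True,
    )
    return out.astype(np.float32)


def normalize_image(image01: np.ndarray) -> np.ndarray:
    """(h, w, 3) in [0,1] -> channel-normalized (3, h, w)."""
    out = (image01 - IMAGENET_MEAN) / IMAGENET_STD
    return np.ascontiguousarray(out.transpose(2, 0, 1)).astype(np.float32)


class SegNet(nn.Module):
    """Two-level UNet-style encoder-decoder with a 4-channel head."""

    def __init__(self, base: int = 12, rng=None):
        rng = rng or np.random.default_rng(0)
        self.base = base
        c0, c1, c2 = base, base * 2, int(base * 8 // 3)
        self.enc0 = nn.ConvBlock(3, c0, rng=rng)
        self.enc1 = nn.ConvBlock(c0, c1, rng=rng)
        self.mid = nn.ConvBlock(c1, c2, rng=rng)
        self.dec1 = nn.ConvBlock(c2 + c1, c1, rng=rng)
        self.dec0 = nn.ConvBlock(c1 + c0, c0, rng=rng)
        self.head = nn.Conv2d(c0, 4, k=3, rng=rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        e0 = self.enc0(x)
        e1 = self.enc1(F.avg_pool2d(e0, 2, 2))
        mid = self.mid(F.avg_pool2d(e1, 2, 2))
        u1 = F.resize_bilinear(mid, *e1.shape[1:])
        d1 = self.dec1(F.concat([u1, e1]))
        u0 = F.resize_bilinear(d1, *e0.shape[1:])
        d0 = self.dec0(F.concat([u0, e0]))
        return self.head(d0)


def semantic_forward(image: RingImage, model: SegNet,
                     config: RunConfig = None) -> SemanticOutput:
    """Run the segmentation net on the downscaled, normalized image."""
    config = config or RunConfig()
    ds = downscale_image(image.pixels, config.downscale)
    if min(ds.shape[:2]) < 8:
        raise ValueError("downscaled input below the network's minimum size")
    x = nn.Tensor(normalize_image(ds))
    return SemanticOutput(logits=model(x).data)


def dice_loss(pred_prob, target, eps: float = 1.0, conventional: bool = False):
    """Binary dice loss, 1 - (sum(y*yhat)+eps)/(sum(y+yhat)+eps).

    ``conventional=True`` switches the numerator to the usual
    2*intersection form.  Accepts Tensors (differentiable) or arrays;
    shapes must match and the target must be binary.
    """
    is_tensor = isinstance(pred_prob, nn.Tensor)
    t = target.data if isinstance(target, nn.Tensor) else np.asarray(target)
    p_shape = pred_prob.shape
    if tuple(p_shape) != tuple(t.shape):
        raise ValueError(f"shape mismatch: {p_shape} vs {t.shape}")
    if eps <= 0:
        raise ValueError("eps must be positive")
    t = nn.Tensor(t.astype(np.float32))
    p = pred_prob if is_tensor else nn.Tensor(np.asarray(pred_prob, np.float32))
    inter = (p * t).sum()
    total = (p + t).sum()
    if conventional:
        loss = 1.0 - (2.0 * inter + eps) / (total + eps)
    else:
        loss = 1.0 - (inter + eps) / (total + eps)
    return loss if is_tensor else float(loss.data)


def seg_total_loss(logits: nn.Tensor, targets: dict, config: RunConfig = None):
    """Weighted sum of per-class dice losses.

    Three classes carry the method's weights (pith 0.1, background
    0.01, boundary 1); the ring class is trained with its own
    configurable weight (default = the background weight).
    """
    config = config or RunConfig()
    weights = {
        "pith": config.alpha_pith,
        "background": config.alpha_background,
        "ring": config.alpha_ring,
        "boundary": config.alpha_boundary,
    }
    total = None
    for i, name in enumerate(SemanticOutput.CLASSES):
        if name not in targets:
            raise KeyError(f"missing target channel '{name}'")
        prob = logits[i].sigmoid()
        term = dice_loss(
            prob, targets[name], eps=config.dice_eps,
            conventional=config.dice_conventional,
        ) * weights[name]
        total = term if total is None else total + term
    return total


def derive_semantic_targets(mask: InstanceMask, pith_disk=None,
                            boundary_width_px: int = 3, factor: int = 4):
    """Binary target masks at the downscaled resolution.

    boundary = dilated interfaces between consecutive rings plus the
    outer xylem edge; ring = union of ring labels; background = outside
    the xylem; pith = provided disk or the region enclosed by the
    innermost ring.
    """
    n = mask.n_rings
    if n < 1:
        raise ValueError("mask contains zero rings")
    if boundary_width_px < 1:
        raise ValueError("boundary_width_px must be >= 1")
    h, w = mask.shape
    ds_idx_r = np.clip(
        np.round(np.arange(h // factor) * factor + (factor - 1) / 2).astype(int),
        0, h - 1,
    )
    ds_idx_c = np.clip(
        np.round(np.arange(w // factor) * factor + (factor - 1) / 2).astype(int),
        0, w - 1,
    )
    labels = mask.labels[np.ix_(ds_idx_r, ds_idx_c)]

    rings = labels > 0
    filled = ndi.binary_fill_holes(rings)
    background = ~filled
    if pith_disk is not None:
        pith = np.asarray(pith_disk, dtype=bool)
        if pith.shape != labels.shape:
            raise ValueError("pith_disk must be at downscaled resolution")
    else:
        pith = filled & ~rings

    boundary = np.zeros_like(rings)
    interior = filled & ~rings
    for k in range(1, n + 1):
        # outer edge of rings 1..k (pith hole filled so the pith/ring-1
        # interface is not part of the boundary class)
        member = interior | ((labels >= 1) & (labels <= k))
        boundary |= member & ~ndi.binary_erosion(member)
    n_dilate = (boundary_width_px - 1) // 2
    if n_dilate > 0:
        boundary = ndi.binary_dilation(
            boundary, structure=ndi.generate_binary_structure(2, 2),
            iterations=n_dilate,
        )
    return {
        "pith": pith,
        "background": background,
        "ring": rings,
        "boundary": boundary,
    }


def extract_pith(output: SemanticOutput, threshold: float = 0.5):
    """Pith center and initial boundary from the pith probability map.

    Binarizes at ``threshold``, keeps the largest connected component,
    and returns its centroid plus the outer contour resampled to M
    equally spaced angles (M from the adaptive angular resolution at
    the component's mean radius).  Raises PithNotFoundError when no
    pixel clears the threshold.
    """
    mask = output.prob("pith") >= threshold
    if not mask.any():
        raise PithNotFoundError("no pith pixel above threshold")
    comps = cc_label(mask)
    sizes = np.bincount(comps.ravel())
    sizes[0] = 0
    comp = comps == sizes.argmax()
    rows, cols = np.nonzero(comp)
    center = np.array([rows.mean(), cols.mean()])

    fine = 360
    angles = 2 * np.pi * np.arange(fine) / fine
    radii = ray_march_outer(comp, center, angles, float(np.hypot(*mask.shape)))
    radii = np.where(np.isnan(radii), 0.5, np.maximum(radii, 0.5))
    probe = BoundaryPolyline(center, radii)
    m = adaptive_angular_resolution(probe)
    return center, probe.resample(m)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _augment(image_chw, targets, rng):
    """Random flips/rot90 plus mild color jitter (applied consistently)."""
    k = rng.integers(0, 4)
    flip = rng.uniform() < 0.5
    def tf(a, spatial_axes):
        a = np.rot90(a, k, axes=spatial_axes)
        if flip:
            a = np.flip(a, axis=spatial_axes[1])
        return np.ascontiguousarray(a)
    img = tf(image_chw, (1, 2))
    img = img * rng.uniform(0.9, 1.1) + rng.normal(0, 0.05)
    tgt = {k2: tf(v, (0, 1)) for k2, v in targets.items()}
    return img.astype(np.float32), tgt


def train_segmentation(samples, config: RunConfig = None, rng=None,
                       epochs=None, log=None):
    """Train a SegNet on (RingImage, InstanceMask) pairs.

    Cosine-annealed Adam with gradient accumulation standing in for
    batching; random rotation/flip and color jitter augmentation.
    Returns the trained model.
    """
    config = config or RunConfig()
    rng = rng or np.random.default_rng(config.seed)
    epochs = epochs or config.seg_epochs
    model = SegNet(base=config.seg_channels, rng=rng)
    opt = nn.Adam(model.parameters(), lr=config.lr_start)

    prepared = []
    for image, mask in samples:
        ds = downscale_image(image.pixels, config.downscale)
        x = normalize_image(ds)
        targets = derive_semantic_targets(
            mask, boundary_width_px=config.boundary_width_px,
            factor=config.downscale,
        )
        prepared.append((x, targets))

    losses = []
    for epoch in range(epochs):
        opt.lr = nn.cosine_lr(epoch, epochs, config.lr_start, config.lr_end)
        order = rng.permutation(len(prepared))
        epoch_loss, since_step = 0.0, 0
        opt.zero_grad()
        for idx in order:
            x, targets = prepared[idx]
            x_aug, t_aug = _augment(x, targets, rng)
            logits = model(nn.Tensor(x_aug))
            loss = seg_total_loss(logits, t_aug, config)
            loss.backward()
            epoch_loss += float(loss.data)
            since_step += 1
            if since_step == config.accumulation:
                opt.step()
                opt.zero_grad()
                since_step = 0
        if since_step:
            opt.step()
            opt.zero_grad()
        losses.append(epoch_loss / len(prepared))
        if log is not None:
            log({"epoch": epoch, "loss": losses[-1], "lr": opt.lr})
    model.loss_history = losses
    return model


def save_segnet(model: SegNet, path):
    """Checkpoint a SegNet (weights + width) to .npz."""
    state = model.state_dict()
    state["__base"] = np.array(model.base)
    np.savez(path, **state)


def load_segnet(path) -> SegNet:
    with np.load(path) as data:
        base = int(data["__base"])
        model = SegNet(base=base)
        model.load_state_dict({k: data[k] for k in data.files if k != "__base"})
    return model
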