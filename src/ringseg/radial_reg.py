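"""Radial regression: per-angle distance to the next ring boundary.

The network maps a 6xNxM polar image to M normalized distances (and,
optionally, M Laplace scale parameters for aleatoric uncertainty).  It
is fully convolutional in the angular dimension: convolutions wrap
around circularly, spatial reduction acts only on the radial axis, and
the decoder output is concatenated with the input polar image (feature
bypass) before a radial average pooling (kernel Nx1) collapses the
radial axis; a final 1x1 convolution yields 1 (or 2) channels.  The
whole map is therefore exactly equivariant to angular rotations and
accepts any angular size M >= 8 without reshaping weights.

Target normalization maps row distances d in [0, N] to [-1, 1] via
n(d) = (d - N/2)/(N/2); training minimizes the summed L1 error, or the
Laplace negative log-likelihood when uncertainty is enabled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .config import RunConfig
from .polar import PolarImage

__all__ = [
    "RadialPrediction",
    "RegressionNet",
    "regression_forward",
    "normalize_target",
    "denormalize",
    "l1_loss",
    "laplace_nll_loss",
    "sigma_from_b",
]


def normalize_target(d, n: int):
    """n(d) = (d - N/2)/(N/2): rows in [0, N] -> [-1, 1]."""
    if n <= 0:
        raise ValueError("N must be positive")
    return (np.asarray(d, dtype=float) - n / 2) / (n / 2)


def denormalize(delta, n: int, p: float = None):
    """Inverse of the target normalization.

    Without ``p``: rows.  With ``p``: composed with the ray step P/N,
    giving the distance in downscaled pixels, (delta + 1) * P / 2.
    """
    rows = np.asarray(delta, dtype=float) * (n / 2) + n / 2
    if p is None:
        return rows
    return rows * (p / n)


def sigma_from_b(b, p: float):
    """Laplace scale -> standard deviation in downscaled pixels:
    sigma = sqrt(2) * b * P/2 (Laplace sd = sqrt(2)*scale; P/2 undoes
    the target normalization)."""
    if p <= 0:
        raise ValueError("P must be positive")
    return np.sqrt(2.0) * np.asarray(b, dtype=float) * p / 2.0


@dataclass
class RadialPrediction:
    """Per-angle regression output for one polar image."""

    delta: np.ndarray            # (M,) normalized distances
    p: float                     # ring-width estimate P (downscaled px)
    n: int                       # radial resolution N
    b: np.ndarray | None = None  # (M,) Laplace scales, > 0

    def __post_init__(self):
        self.delta = np.asarray(self.delta, dtype=float)
        if self.b is not None:
            self.b = np.asarray(self.b, dtype=float)
            if self.b.shape != self.delta.shape:
                raise ValueError("delta and b must have equal length")
            if (self.b <= 0).any():
                raise ValueError("Laplace scales must be strictly positive")

    @property
    def m(self) -> int:
        return self.delta.size

    @property
    def d_rows(self) -> np.ndarray:
        return denormalize(self.delta, self.n)

    @property
    def d_px(self) -> np.ndarray:
        return denormalize(self.delta, self.n, self.p)

    @property
    def sigma_px(self) -> np.ndarray | None:
        return None if self.b is None else sigma_from_b(self.b, self.p)


def _masked(t: nn.Tensor, mask):
    if mask is None:
        return t
    idx = np.nonzero(np.asarray(mask))[0]
    return t[idx]


def l1_loss(delta: nn.Tensor, target_norm, mask=None, reduction="sum"):
    """Summed absolute error in normalized units: sum_m |delta_m - n(d_m)|.

    ``mask`` (bool, per column) drops angular positions without a valid
    ground-truth crossing.  ``reduction='mean'`` averages over the kept
    columns for comparability across angular sizes.
    """
    target = np.asarray(target_norm, dtype=np.float32)
    if delta.shape[0] != target.shape[0]:
        raise ValueError("prediction/target length mismatch")
    diff = (_masked(delta, mask) - _masked(nn.Tensor(target), mask)).abs()
    return diff.mean() if reduction == "mean" else diff.sum()


def laplace_nll_loss(delta: nn.Tensor, b: nn.Tensor, target_norm,
                     mask=None, reduction="sum"):
    """Laplace negative log-likelihood:
    sum_m |delta_m - n(d_m)| / b_m + log(b_m).

    A larger b downweights a column's error at the cost of the log
    term; at b = 1 the loss equals the L1 loss.
    """
    target = np.asarray(target_norm, dtype=np.float32)
    if delta.shape[0] != target.shape[0]:
        raise ValueError("prediction/target length mismatch")
    if (b.data <= 0).any():
        raise ValueError("Laplace scales must be strictly positive")
    err = (_masked(delta, mask) - _masked(nn.Tensor(target), mask)).abs()
    bm = _masked(b, mask)
    terms = err / bm + bm.log()
    return terms.mean() if reduction == "mean" else terms.sum()


class RegressionNet(nn.Module):
    """Dilated encoder-decoder over polar images.

    Angular axis: circular convolutions, never strided.  Radial axis:
    two 2x average-pool reductions, a pyramid of dilated convolutions
    (the multi-rate context block, reduced to ``aspp_channels`` filters
    and with no normalization after it), linear radial upsampling back
    to N, a decoder that sees the stem features, the input bypass
    concat, radial average pooling and a 1x1 head.
    """

    def __init__(self, base: int = 16, aspp: int = 64,
                 with_uncertainty: bool = False, b_floor: float = 1e-3,
                 rng=None):
        rng = rng or np.random.default_rng(0)
        self.with_uncertainty = with_uncertainty
        self.b_floor = b_floor
        self.base = base
        self.aspp = aspp
        c0, c1, c2 = base, int(base * 1.5), base * 2
        self.stem = nn.ConvBlock(6, c0, circular=True, rng=rng)
        self.enc1 = nn.ConvBlock(c0, c1, circular=True, rng=rng)
        self.enc2 = nn.ConvBlock(c1, c2, circular=True, rng=rng)
        self.aspp1 = nn.Conv2d(c2, c2 // 2, k=1, rng=rng)
        self.aspp2 = nn.Conv2d(c2, c2 // 2, k=3, dilation=2, circular=True, rng=rng)
        self.aspp3 = nn.Conv2d(c2, c2 // 2, k=3, dilation=4, circular=True, rng=rng)
        self.project = nn.Conv2d(3 * (c2 // 2), aspp, k=1, rng=rng)
        self.decode = nn.ConvBlock(aspp + c2, c2, circular=True, rng=rng)
        self.head = nn.Conv2d(c2 + 6, 2 if with_uncertainty else 1, k=1, rng=rng)

    def __call__(self, polar_data: np.ndarray):
        """(6, N, M) -> (delta Tensor (M,), b Tensor (M,) or None)."""
        x = nn.Tensor(np.asarray(polar_data, dtype=np.float32))
        n = x.shape[1]
        e0 = self.stem(x)
        e1 = self.enc1(F.avg_pool2d(e0, 2, 1))
        e2 = self.enc2(F.avg_pool2d(e1, 2, 1))
        a = F.concat([self.aspp1(e2), self.aspp2(e2), self.aspp3(e2)])
        a = self.project(a).relu()          # no norm after the pyramid block
        d = self.decode(F.concat([a, e2]))  # decoder at the coarse radial res
        d = F.resize_linear(d, n, axis=1)   # radial-only upsampling
        d = F.concat([d, x])                # bypass: re-inject the polar image
        pooled = d.mean(axis=1, keepdims=True)  # radial average pool (Nx1)
        out = self.head(pooled)             # (1 or 2, 1, M)
        delta = out[0][0]
        if not self.with_uncertainty:
            return delta, None
        b = out[1][0].softplus() + self.b_floor
        return delta, b


def regression_forward(polar: PolarImage, model: RegressionNet,
                       config: RunConfig = None) -> RadialPrediction:
    """Run the regression net on a polar image (no gradients retained)."""
    if polar.m < 8:
        raise ValueError("angular size below the network's minimum extent")
    delta, b = model(polar.data)
    return RadialPrediction(
        delta=delta.data.copy(),
        b=None if b is None else b.data.copy(),
        p=polar.p,
        n=polar.n,
    )


def save_regnet(model: RegressionNet, path):
    """Checkpoint a RegressionNet (weights + architecture) to .npz."""
    state = model.state_dict()
    state["__meta"] = np.array(
        [model.base, model.aspp, int(model.with_uncertainty), model.b_floor]
    )
    np.savez(path, **state)


def load_regnet(path) -> RegressionNet:
    with np.load(path) as data:
        base, aspp, unc, floor = data["__meta"]
        model = RegressionNet(
            base=int(base), aspp=int(aspp), with_uncertainty=bool(unc),
            b_floor=float(floor),
        )
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta"})
    return model
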