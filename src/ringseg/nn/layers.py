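"""Layers, modules, optimizer and LR schedule for the tiny CNN stack."""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Parameter, Tensor
from . import functional as F

__all__ = [
    "Module",
    "Conv2d",
    "InstanceNorm2d",
    "ConvBlock",
    "Adam",
    "cosine_lr",
]


class Module:
    """Base class; collects parameters from attributes recursively."""

    def parameters(self):
        params = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- (de)serialization ----------------------------------------------
    def state_dict(self):
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state):
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state size mismatch")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for p{i}")
            p.data = arr

    def save(self, path):
        np.savez(path, **self.state_dict())

    def load(self, path):
        with np.load(path) as data:
            self.load_state_dict(dict(data))


class Conv2d(Module):
    def __init__(self, cin, cout, k=3, dilation=1, circular=False, rng=None):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        std = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, size=(cout, cin, k, k)))
        self.bias = Parameter(np.zeros(cout))
        self.dilation = (dilation, dilation) if np.isscalar(dilation) else dilation
        self.circular = circular

    def __call__(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.dilation, self.circular)


class InstanceNorm2d(Module):
    """Per-channel normalization over the spatial dims of a single sample."""

    def __init__(self, channels, eps=1e-5):
        self.gain = Parameter(np.ones((channels, 1, 1)))
        self.shift = Parameter(np.zeros((channels, 1, 1)))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(1, 2), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(1, 2), keepdims=True)
        inv = F.pow_(var + self.eps, -0.5)
        return xc * inv * self.gain + self.shift


class ConvBlock(Module):
    """conv -> instance norm -> ReLU."""

    def __init__(self, cin, cout, k=3, dilation=1, circular=False, rng=None):
        self.conv = Conv2d(cin, cout, k, dilation, circular, rng)
        self.norm = InstanceNorm2d(cout)

    def __call__(self, x: Tensor) -> Tensor:
        return self.norm(self.conv(x)).relu()


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def cosine_lr(epoch, n_epochs, lr_start=1e-3, lr_end=1e-5):
    """Cosine-annealed learning rate from lr_start down to lr_end."""
    if n_epochs <= 1:
        return lr_start
    t = epoch / (n_epochs - 1)
    return lr_end + 0.5 * (lr_start - lr_end) * (1 + math.cos(math.pi * t))
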