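"""Run configuration with the method's default hyperparameters.

Every hyperparameter of the method with its default: dice loss weights
``alpha_pith=0.1``, ``alpha_background=0.01``, ``alpha_boundary=1.0``;
polar radial resolution ``N=256``; unrolling depth ``K=3``; calibration
bin count ``U=100``; semantic model operating at a x4 downscale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # geometry
    downscale: int = 4
    polar_n: int = 256          # radial points N in the polar image
    max_angular: int | None = None  # optional cap on M for desk-scale runs
    max_iterations: int = 200   # hard safety cap for the iterative loop
    min_advance_px: float = 0.1  # stop when the boundary no longer moves

    # ring width estimate (P)
    ring_width_factor: float = 1.5
    ring_width_percentile: float = 95.0
    ring_width_blank_px: float = 2.0   # skip the current boundary's own mass
    ring_width_hit_fraction: float = 0.2  # below this: "absent" -> stop

    # semantic segmentation
    alpha_pith: float = 0.1
    alpha_background: float = 0.01
    alpha_boundary: float = 1.0
    alpha_ring: float = 0.01   # the dice weighting names only three classes
    dice_eps: float = 1.0
    dice_conventional: bool = False  # True: 2*intersection numerator
    boundary_width_px: int = 3       # target thickness at downscaled res
    pith_threshold: float = 0.5
    seg_epochs: int = 1000
    seg_channels: int = 12           # base width of the segmentation net

    # radial regression
    unroll_k: int = 3                # K
    reg_epochs: int = 500
    reg_channels: int = 16           # base width of the regression net
    aspp_channels: int = 64          # filters after the pyramid-pooling block
    accumulation: int = 8            # gradient accumulation = emulated batch
    loss_reduction: str = "sum"      # summed over angles; "mean" optional
    with_uncertainty: bool = False
    b_floor: float = 1e-3            # softplus floor for the Laplace scale
    absent_column_fraction: float = 0.5  # majority rule for "absent" targets

    # optimization
    lr_start: float = 1e-3
    lr_end: float = 1e-5

    # evaluation
    ence_bins: int = 100             # U
    ence_variant: str = "variance"    # or "standard"

    # rendering / misc
    pith_label: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.polar_n < 4:
            raise ValueError("polar_n must be >= 4")
        if self.downscale < 1:
            raise ValueError("downscale must be >= 1")
        if self.unroll_k < 1:
            raise ValueError("unroll_k must be >= 1")
        if self.loss_reduction not in ("sum", "mean"):
            raise ValueError("loss_reduction must be 'sum' or 'mean'")
        if self.ence_variant not in ("variance", "standard"):
            raise ValueError("ence_variant must be 'variance' or 'standard'")

    # -- serialization ---------------------------------------------------
    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
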