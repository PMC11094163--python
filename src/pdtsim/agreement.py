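"""Tumor-volume arithmetic and Bland-Altman method agreement.

The caliper tumor-volume formula V = L * W^2 / 2 and the Bland-Altman
analysis used to compare ultrasound against vernier-caliper volume
measurements: bias (mean paired difference) and 95% limits of agreement
bias +/- 1.96 * SD of the differences (sample SD, normal-quantile
multiplier).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["CaliperPair", "BlandAltmanResult", "tumor_volume", "bland_altman"]


@dataclass(frozen=True)
class CaliperPair:
    """Caliper axes in mm; by convention length is the larger axis."""

    length: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"width must be > 0, got {self.width}")
        if self.length < self.width:
            raise ValueError(
                f"length ({self.length}) must be >= width ({self.width}); axes swapped?"
            )


def tumor_volume(pair: CaliperPair) -> float:
    """Tumor volume (mm^3) = length * width^2 * 0.5."""
    return pair.length * pair.width**2 * 0.5


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 95% limits of agreement between two paired methods.

    All of bias, SD of differences, both limits, and the half-width
    (1.96 * SD) are exposed so any single-number convention is
    recoverable.
    """

    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    n: int

    @property
    def loa_half_width(self) -> float:
        return 1.96 * self.sd_diff

    def to_dict(self) -> dict:
        return {
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "loa_half_width": self.loa_half_width,
            "n": self.n,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def bland_altman(
    method_a: Sequence[float], method_b: Sequence[float]
) -> BlandAltmanResult:
    """Bland-Altman agreement of two equal-length paired measurement sets.

    bias = mean(a - b); limits = bias +/- 1.96 * sd(a - b) with the
    sample (n-1) standard deviation.  Requires n >= 2.
    """
    a = np.asarray(method_a, float)
    b = np.asarray(method_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"paired 1-D samples required, got shapes {a.shape}, {b.shape}")
    if a.size < 2:
        raise ValueError(f"need at least 2 pairs, got {a.size}")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    half = 1.96 * sd
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - half,
        loa_upper=bias + half,
        n=int(a.size),
    )
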