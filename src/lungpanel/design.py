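"""Cluster-adjusted sample size for estimating an agreement proportion.

Recordings are clustered within patients (fixed cluster size m), so the
variance of an agreement proportion is inflated by the design effect
DEFF = 1 + (m - 1) * ICC. The participant count needed for a two-sided
confidence interval of half-width d around an anticipated proportion p is

    n = ceil( DEFF * z^2 * p(1-p) / d^2 )

with z the two-sided normal quantile at the chosen confidence level and
the ceiling applied once, last.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy import stats as _stats

from .errors import ValidationError

__all__ = ["DesignInputs", "design_effect", "sample_size"]


@dataclass(frozen=True)
class DesignInputs:
    p: float
    halfwidth: float
    m: int = 1
    icc: float = 0.0
    conf: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ValidationError("p must be in (0, 1)")
        if not 0 < self.halfwidth < 1:
            raise ValidationError("halfwidth must be in (0, 1)")
        if self.m < 1:
            raise ValidationError("cluster size m must be >= 1")
        if not 0 <= self.icc <= 1:
            raise ValidationError("icc must be in [0, 1]")
        if not 0 < self.conf < 1:
            raise ValidationError("conf must be in (0, 1)")


def design_effect(m: int, icc: float) -> float:
    """Variance inflation 1 + (m-1)*ICC for clusters of size m."""
    if m < 1:
        raise ValidationError("cluster size m must be >= 1")
    if not 0 <= icc <= 1:
        raise ValidationError("icc must be in [0, 1]")
    return 1 + (m - 1) * icc


def sample_size(design: DesignInputs) -> int:
    """Participants needed for the requested precision under clustering.

    Warns (and still computes) when the half-width exceeds the distance
    from p to the nearer boundary, since the target interval would cross
    0 or 1.
    """
    if design.halfwidth >= min(design.p, 1 - design.p):
        warnings.warn(
            "requested half-width reaches beyond [0, 1] around p; "
            "the interval will be truncated",
            stacklevel=2,
        )
    z = float(_stats.norm.ppf(0.5 + design.conf / 2))
    deff = design_effect(design.m, design.icc)
    n = deff * z**2 * design.p * (1 - design.p) / design.halfwidth**2
    return math.ceil(n)
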