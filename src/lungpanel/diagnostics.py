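"""Diagnostic accuracy of an index classifier against a reference standard.

From a 2x2 table (see :mod:`lungpanel.concordance` for cell layout, with
the reference standard on rows): sensitivity a/(a+c), specificity
d/(b+d), predictive values, likelihood ratios LR+ = sens/(1-spec) and
LR- = (1-sens)/spec, and the diagnostic odds ratio ad/(bc).

Proportion confidence intervals are exact Clopper-Pearson; ratio
intervals are normal on the log scale with the usual delta-method
standard errors. A ratio made undefined by a zero cell is reported as an
explicit undefined estimate, never a silent infinity; an optional
Haldane-Anscombe 0.5 continuity correction yields finite values instead,
behind a flag and never by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

from scipy import stats as _stats

from .annotations import Status
from .concordance import ContingencyTable
from .errors import ValidationError

__all__ = [
    "Estimate",
    "DiagnosticResult",
    "clopper_pearson",
    "diagnostic_metrics",
    "metrics_from_pairs",
]


@dataclass(frozen=True)
class Estimate:
    """A point estimate with a confidence interval; either may be undefined."""

    value: Optional[float]
    ci: Optional[Tuple[float, float]] = None

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclass(frozen=True)
class DiagnosticResult:
    sens: Estimate
    spec: Estimate
    ppv: Estimate
    npv: Estimate
    lr_pos: Estimate
    lr_neg: Estimate
    dor: Estimate
    abnormal_fraction_index: float
    n: int


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> Tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for k/n."""
    if not 0 <= k <= n or n < 1:
        raise ValidationError(f"invalid binomial counts k={k}, n={n}")
    alpha = 1 - conf
    lo = 0.0 if k == 0 else float(_stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(_stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def _proportion(k: int, n: int, conf: float) -> Estimate:
    if n == 0:
        return Estimate(value=None)
    return Estimate(value=k / n, ci=clopper_pearson(k, n, conf))


def _log_ratio(value: Optional[float], se_terms, conf: float) -> Estimate:
    """CI for a positive ratio: normal on the log scale.

    ``se_terms`` are the signed 1/cell contributions to var(ln ratio);
    the interval is undefined when the point is undefined/zero or any
    denominator in the variance is zero.
    """
    if value is None:
        return Estimate(value=None)
    if value == 0 or any(cell == 0 for _, cell in se_terms):
        return Estimate(value=value, ci=None)
    var = sum(sign / cell for sign, cell in se_terms)
    if var < 0:
        return Estimate(value=value, ci=None)
    z = float(_stats.norm.ppf(0.5 + conf / 2))
    half = z * math.sqrt(var)
    return Estimate(
        value=value,
        ci=(value * math.exp(-half), value * math.exp(half)),
    )


def diagnostic_metrics(
    t: ContingencyTable,
    conf: float = 0.95,
    continuity_correction: bool = False,
) -> DiagnosticResult:
    """All diagnostic-accuracy metrics for one 2x2 table.

    Requires at least one reference-positive and one reference-negative
    pair. With ``continuity_correction`` the ratio metrics (only) are
    computed on a table with 0.5 added to every cell whenever any cell
    is zero.
    """
    if t.a + t.c < 1 or t.b + t.d < 1:
        raise ValidationError(
            "diagnostic metrics need both reference statuses represented"
        )
    a, b, c, d = t.a, t.b, t.c, t.d
    sens = _proportion(a, a + c, conf)
    spec = _proportion(d, b + d, conf)
    ppv = _proportion(a, a + b, conf)
    npv = _proportion(d, c + d, conf)

    fa, fb, fc, fd = (float(a), float(b), float(c), float(d))
    if continuity_correction and min(a, b, c, d) == 0:
        fa, fb, fc, fd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    fse, fsp = fa / (fa + fc), fd / (fb + fd)

    lr_pos_val = fse / (1 - fsp) if fsp < 1 else None
    lr_neg_val = (1 - fse) / fsp if fsp > 0 else None
    dor_val = (fa * fd) / (fb * fc) if fb * fc > 0 else None

    lr_pos = _log_ratio(
        lr_pos_val,
        ((1, fa), (-1, fa + fc), (1, fb), (-1, fb + fd)),
        conf,
    )
    lr_neg = _log_ratio(
        lr_neg_val,
        ((1, fc), (-1, fa + fc), (1, fd), (-1, fb + fd)),
        conf,
    )
    dor = _log_ratio(dor_val, ((1, fa), (1, fb), (1, fc), (1, fd)), conf)

    return DiagnosticResult(
        sens=sens,
        spec=spec,
        ppv=ppv,
        npv=npv,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        dor=dor,
        abnormal_fraction_index=(a + b) / t.n,
        n=t.n,
    )


def metrics_from_pairs(
    pairs: Iterable[Tuple[Status, Status]],
    conf: float = 0.95,
    continuity_correction: bool = False,
) -> DiagnosticResult:
    """Tabulate (reference, index) pairs and delegate to
    :func:`diagnostic_metrics`."""
    t = ContingencyTable.from_pairs(pairs)
    return diagnostic_metrics(t, conf=conf, continuity_correction=continuity_correction)
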