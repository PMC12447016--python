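"""Chance-adjusted agreement statistics for paired binary classifications.

Works on a 2x2 cross-classification of reference (rows) by index
(columns) abnormal/normal counts:

    a = both abnormal            b = index abnormal, reference normal
    c = index normal, ref abnormal   d = both normal

Provides raw agreement, Cohen's kappa (margin-based chance agreement),
and the Brennan-Prediger statistic (fixed 1/q chance level, robust to
skewed margins; for two categories it equals 2*po - 1). Standard errors
use the large-sample form sqrt(po(1-po)/n) scaled by 1/(1-pe) for kappa
and 1/(1-1/q) for Brennan-Prediger; confidence bounds are clamped to
[-1, 1]. Clustering of positions within patients is deliberately not
adjusted for here; it enters only the study-design module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

from scipy import stats as _stats

from .annotations import Status
from .errors import DegenerateStatisticsError, ValidationError

__all__ = [
    "ContingencyTable",
    "AgreementResult",
    "KappaResult",
    "BPResult",
    "reconstruct_table",
    "raw_agreement",
    "cohen_kappa",
    "brennan_prediger",
    "classify_strength",
    "agreement_statistics",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 reference-by-index table of abnormal/normal counts."""

    a: int  # both abnormal
    b: int  # index abnormal, reference normal
    c: int  # index normal, reference abnormal
    d: int  # both normal

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency cells must be non-negative")
        if self.n < 1:
            raise ValidationError("contingency table must contain at least one pair")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def reference_positive(self) -> int:
        return self.a + self.c

    @property
    def index_positive(self) -> int:
        return self.a + self.b

    @property
    def agreement(self) -> int:
        return self.a + self.d

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(a=self.a, b=self.c, c=self.b, d=self.d)

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[Tuple[Status, Status]]
    ) -> "ContingencyTable":
        """Tabulate (reference, index) status pairs."""
        a = b = c = d = 0
        for ref, idx in pairs:
            if ref is Status.ABNORMAL:
                if idx is Status.ABNORMAL:
                    a += 1
                else:
                    c += 1
            else:
                if idx is Status.ABNORMAL:
                    b += 1
                else:
                    d += 1
        return cls(a=a, b=b, c=c, d=d)


def reconstruct_table(
    n: int, reference_positive: int, index_positive: int, agreement: int
) -> ContingencyTable:
    """Invert printed marginals (N, reference-abnormal, index-abnormal,
    agreements) into the unique 2x2 table they determine.

    Solves a+b = index_positive, a+c = reference_positive, a+d =
    agreement, a+b+c+d = n. Raises on parity violation (no integer
    solution) or a negative cell.
    """
    if min(n, reference_positive, index_positive, agreement) < 0:
        raise ValidationError("marginals must be non-negative")
    if max(reference_positive, index_positive, agreement) > n:
        raise ValidationError("marginals cannot exceed n")
    num = reference_positive + index_positive + agreement - n
    if num % 2 != 0:
        raise ValidationError(
            f"inconsistent marginals ({n}, {reference_positive}, "
            f"{index_positive}, {agreement}): no integer table exists"
        )
    a = num // 2
    t = dict(
        a=a,
        b=index_positive - a,
        c=reference_positive - a,
        d=agreement - a,
    )
    if min(t.values()) < 0:
        raise ValidationError(
            f"inconsistent marginals ({n}, {reference_positive}, "
            f"{index_positive}, {agreement}): negative cell {t}"
        )
    return ContingencyTable(**t)


def raw_agreement(t: ContingencyTable) -> float:
    """Observed proportion of agreeing pairs, (a+d)/n."""
    return (t.a + t.d) / t.n


def _z(conf: float) -> float:
    return float(_stats.norm.ppf(0.5 + conf / 2))


def _clamp_ci(point: float, se: float, conf: float) -> Tuple[float, float]:
    z = _z(conf)
    return (max(point - z * se, -1.0), min(point + z * se, 1.0))


@dataclass(frozen=True)
class KappaResult:
    po: float
    pe: float
    kappa: float
    se: float
    ci: Tuple[float, float]


@dataclass(frozen=True)
class BPResult:
    po: float
    bp: float
    se: float
    ci: Tuple[float, float]


def cohen_kappa(t: ContingencyTable, conf: float = 0.95) -> KappaResult:
    """Cohen's kappa with a large-sample standard error.

    pe is the margin-product chance agreement
    [(a+b)(a+c) + (c+d)(b+d)] / n^2. Raises
    :class:`DegenerateStatisticsError` when pe = 1 (both raters
    constant).
    """
    n = t.n
    po = raw_agreement(t)
    pe = ((t.a + t.b) * (t.a + t.c) + (t.c + t.d) * (t.b + t.d)) / n**2
    if pe >= 1.0:
        raise DegenerateStatisticsError(
            "chance agreement is 1 (both raters constant); kappa undefined"
        )
    kappa = (po - pe) / (1 - pe)
    se = math.sqrt(po * (1 - po) / n) / (1 - pe)
    return KappaResult(po=po, pe=pe, kappa=kappa, se=se, ci=_clamp_ci(kappa, se, conf))


def brennan_prediger(
    t: ContingencyTable, q: int = 2, conf: float = 0.95
) -> BPResult:
    """Brennan-Prediger chance-adjusted agreement with fixed 1/q chance.

    For q = 2 this is exactly 2*po - 1.
    """
    if q < 2:
        raise ValidationError("Brennan-Prediger requires at least 2 categories")
    po = raw_agreement(t)
    bp = (po - 1 / q) / (1 - 1 / q)
    se = math.sqrt(po * (1 - po) / t.n) / (1 - 1 / q)
    return BPResult(po=po, bp=bp, se=se, ci=_clamp_ci(bp, se, conf))


# Half-open strength bins; cuts fall midway between the conventional
# rounded bounds (0.19/0.20 etc.) so every value in [-1, 1] has a bin.
_STRENGTH_BINS: Sequence[Tuple[float, str]] = (
    (0.0, "poor"),
    (0.195, "slight"),
    (0.395, "fair"),
    (0.595, "moderate"),
    (0.795, "substantial"),
    (1.0, "almost perfect"),
)


def classify_strength(statistic: float) -> str:
    """Bin a chance-adjusted agreement value into its strength category."""
    if not -1.0 <= statistic <= 1.0:
        raise ValidationError(f"agreement statistic {statistic} outside [-1, 1]")
    for upper, name in _STRENGTH_BINS:
        if statistic <= upper:
            return name
    return "almost perfect"  # unreachable; appeases type checkers


@dataclass(frozen=True)
class AgreementResult:
    """Full agreement summary for one paired comparison."""

    po: float
    pe: float
    kappa: float
    kappa_se: float
    kappa_ci: Tuple[float, float]
    bp: float
    bp_se: float
    bp_ci: Tuple[float, float]
    strength_kappa: str
    strength_bp: str


def agreement_statistics(
    t: ContingencyTable, conf: float = 0.95, q: int = 2
) -> AgreementResult:
    """Compute every agreement statistic for a 2x2 table at once."""
    k = cohen_kappa(t, conf=conf)
    b = brennan_prediger(t, q=q, conf=conf)
    return AgreementResult(
        po=k.po,
        pe=k.pe,
        kappa=k.kappa,
        kappa_se=k.se,
        kappa_ci=k.ci,
        bp=b.bp,
        bp_se=b.se,
        bp_ci=b.ci,
        strength_kappa=classify_strength(k.kappa),
        strength_bp=classify_strength(b.bp),
    )
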