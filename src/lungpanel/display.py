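"""Display-rounding conventions.

Clinical tables conventionally round half away from zero (96.25% prints
as 96.3), whereas Python's built-in ``round`` is half-to-even. All
human-readable output goes through :func:`round_half_up`.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "fmt"]


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero, on the decimal rendering."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def fmt(value: float, ndigits: int) -> str:
    return f"{round_half_up(value, ndigits):.{ndigits}f}"
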