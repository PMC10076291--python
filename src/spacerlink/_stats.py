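"""Small reporting helpers: round-half-up formatting used in summaries."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.115 -> 0.12), unlike banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(k: float, n: float, ndigits: int = 1) -> float:
    """k/n as a percentage rounded half-up (19/59 -> 32.2; 70/17057 -> 0.41@2)."""
    if n == 0:
        return 0.0
    return round_half_up(100.0 * k / n, ndigits)


def mean(values: Sequence[float]) -> float:
    return sum(values) / len(values)


def median(values: Sequence[float]) -> float:
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2.0
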