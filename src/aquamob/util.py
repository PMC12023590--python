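"""Small shared helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def pct(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """Percentage rounded half-up, the convention used in all summaries."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    q = Decimal(1).scaleb(-ndigits)
    value = Decimal(str(numerator)) * 100 / Decimal(str(denominator))
    return float(value.quantize(q, rounding=ROUND_HALF_UP))
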