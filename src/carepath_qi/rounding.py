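"""Half-away-from-zero percentage rounding used throughout reporting."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (SPSS/spreadsheet convention).

    Python's builtin ``round`` is banker's rounding; reported percentages
    follow the half-away-from-zero convention instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Exact-ratio percentage rounded half-away-from-zero to ``ndigits``."""
    if denominator <= 0:
        raise ZeroDivisionError("percentage undefined for empty denominator")
    q = Decimal(1).scaleb(-ndigits)
    val = Decimal(100 * numerator) / Decimal(denominator)
    return float(val.quantize(q, rounding=ROUND_HALF_UP))
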