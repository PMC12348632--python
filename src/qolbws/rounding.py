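"""Decimal rounding used for all published-table arithmetic.

Printed survey tables round half away from zero (59.615 -> 59.62,
-0.2435 -> -0.244), which differs from Python's banker's rounding.
"""

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_away"]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero.

    Uses :class:`decimal.Decimal` on the shortest repr of ``x`` so that
    values like ``2.675`` behave as written, not as their binary float.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))
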