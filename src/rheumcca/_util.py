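"""Small numeric helpers shared across modules.

Money is carried as floats during computation and snapped to currency minor
units (cents) only when a :class:`~rheumcca.cost_engine.CostBreakdown` is
assembled, using decimal half-up rounding so that additivity checks are exact.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round ``value`` half-up (commercial rounding) to ``ndigits`` decimals.

    Python's builtin ``round`` is banker's rounding; printed price tables use
    half-up, so 2.775 -> 2.78.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def round_half_up_int(value: float) -> int:
    """Round to the nearest integer, halves away from zero upward."""
    return int(Decimal(repr(value)).quantize(Decimal(1), rounding=ROUND_HALF_UP))


def to_cents(value: float) -> int:
    """Snap a money amount to integer minor units (half-up)."""
    return int(
        Decimal(repr(value)).scaleb(2).quantize(Decimal(1), rounding=ROUND_HALF_UP)
    )
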