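"""Single home for percentage formatting.

Every percentage the package prints is rounded here, half-up to one
decimal, so that printed tables are reproducible and the rounding rule
is auditable in one place.  Raw (unrounded) values are always kept
alongside wherever a rounded value is reported.
"""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up_1dp(x: float) -> float:
    """Round to one decimal place, ties away from zero (half-up).

    ``round()`` uses banker's rounding, which disagrees with how
    percentages are conventionally printed in tables (e.g. 5.25 -> 5.3,
    not 5.2).
    """
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def percent(count: float, total: float) -> float:
    """Unrounded percentage ``100 * count / total``."""
    if total == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    return 100.0 * count / total


def percent_1dp(count: float, total: float) -> float:
    """Percentage rounded half-up to one decimal, as printed in tables."""
    return round_half_up_1dp(percent(count, total))
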