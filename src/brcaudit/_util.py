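"""Shared numeric helpers.

All user-facing percentages in this package are rounded half-up (so 0.05
rounds to 0.1, 27.659 rounds to 28), computed with exact decimal division
rather than binary floats to keep printed tables reproducible.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def pct(numerator: int | float, denominator: int | float, ndigits: int = 1) -> float | int:
    """Exact percentage ``100 * numerator / denominator`` rounded half-up.

    Returns an ``int`` when ``ndigits == 0``, otherwise a ``float`` with
    ``ndigits`` decimals.
    """
    if denominator == 0:
        raise ValueError("percentage of an empty total is undefined")
    value = (Decimal(str(numerator)) * 100) / Decimal(str(denominator))
    quantum = Decimal(1).scaleb(-ndigits)
    rounded = value.quantize(quantum, rounding=ROUND_HALF_UP)
    return int(rounded) if ndigits == 0 else float(rounded)


def round_half_up(value: float, ndigits: int = 0) -> float | int:
    """Round a number half-up (unlike Python's banker's rounding)."""
    quantum = Decimal(1).scaleb(-ndigits)
    rounded = Decimal(str(value)).quantize(quantum, rounding=ROUND_HALF_UP)
    return int(rounded) if ndigits == 0 else float(rounded)
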