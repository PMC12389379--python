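"""Rounding and percentage formatting shared across report tables.

All displayed numbers use round-half-up at the displayed precision;
rounding is applied only at formatting time, never inside computations.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties away from zero-half up.

    Python's builtin ``round`` is banker's rounding; report tables in the
    bibliometric literature round 0.5 up, so we go through ``decimal``.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def share_pct(part: float, total: float, ndigits: int = 2) -> float:
    """Percentage share ``100 * part / total`` rounded half-up.

    Raises ``ZeroDivisionError`` for a zero total: callers decide how an
    empty denominator is reported.
    """
    return round_half_up(100.0 * part / total, ndigits)


def format_percent(part: float, total: float, ndigits: int = 2) -> str:
    """Render a share as e.g. ``"87.76%"`` or ``"5%"`` (ndigits=0)."""
    value = share_pct(part, total, ndigits)
    if ndigits == 0:
        return f"{int(value)}%"
    return f"{value:.{ndigits}f}%"
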