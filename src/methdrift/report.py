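"""Report formatting: percentage and density rounding rules.

All human-readable numbers round half away from zero at the displayed
precision — integers for percentages of counts, one decimal for mean
densities and gene-fraction percentages. Internal values are kept at full
precision; formatting owns all rounding.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_away", "fmt_percent", "fmt_number"]


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero at ``decimals`` decimal places."""
    q = Decimal(1).scaleb(-decimals)
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


def fmt_number(x: float, decimals: int = 1) -> str:
    return f"{round_half_away(x, decimals):.{decimals}f}"


def fmt_percent(numerator: float, denominator: float, decimals: int = 0) -> str:
    """Format ``numerator/denominator`` as a percent string, e.g. ``"89%"``
    or ``"4.7%"``."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    pct = 100.0 * numerator / denominator
    if decimals == 0:
        return f"{round_half_away(pct, 0):.0f}%"
    return f"{round_half_away(pct, decimals):.{decimals}f}%"
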