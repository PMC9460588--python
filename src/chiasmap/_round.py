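"""Half-up decimal rounding for report display.

Internal computation is always unrounded; values are rounded half-up
(0.005 -> 0.01) only when written into reports, matching the published
tables' formatting rather than banker's rounding.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 2) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def format_half_up(value: float, ndigits: int = 2) -> str:
    q = Decimal(10) ** -ndigits
    return str(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))
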