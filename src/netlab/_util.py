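"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Half-up decimal rounding (3.0769 -> 3.1; 1.625 -> 1.6 at one decimal)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def fmt1(x: float) -> str:
    """Render to one decimal with half-up rounding, as in the printed tables."""
    return f"{round_half_up(x, 1):.1f}"
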