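"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_away"]


def round_half_away(x: float, digits: int = 1) -> float:
    """Round with ties going away from zero (reporting convention)."""
    quantum = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))
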