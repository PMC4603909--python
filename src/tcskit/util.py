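"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_away"]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with halves going away from zero (printed-table convention).

    Python's built-in ``round`` is banker's rounding; summary tables in this
    package use the conventional 0.5-up rule instead, e.g. 2.25 -> 2.3.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
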