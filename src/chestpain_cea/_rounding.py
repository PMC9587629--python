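"""Reporting-boundary rounding.

Values are carried unrounded internally; rounding happens only when a
number is rendered the way the study prints it (whole EUR for costs,
five decimals for QALYs).  Half-way cases round away from zero, which is
what reproduces the printed cells (e.g. 12.532 → 13).
"""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round to ``ndigits`` decimals, ties away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_eur(x: float) -> int:
    """Whole-EUR reporting rounding."""
    return int(round_half_up(x, 0))


def round_qaly(x: float) -> float:
    """Five-decimal QALY reporting rounding."""
    return round_half_up(x, 5)
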