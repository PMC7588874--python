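"""Report-time rounding conventions.

All internal quantities are kept at full precision; rounding happens once,
at report time.  Two conventions are used:

* nonnegative rates, averages and ratios round half-up (the convention of
  printed tables, where a tie moves away from zero);
* signed differences round half-to-even, the unbiased tie-break for
  quantities whose sign carries meaning.

Both operate on the shortest decimal representation of the float (its
``repr``), so binary representation dust one ulp away from a decimal tie
does not flip the reported digit.
"""

from __future__ import annotations

from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "round_half_even"]


def _quantum(ndigits: int) -> Decimal:
    return Decimal(1).scaleb(-ndigits)


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round to ``ndigits`` decimals with ties away from zero."""
    return float(Decimal(repr(float(x))).quantize(_quantum(ndigits), rounding=ROUND_HALF_UP))


def round_half_even(x: float, ndigits: int = 3) -> float:
    """Round to ``ndigits`` decimals with ties to the even digit."""
    return float(Decimal(repr(float(x))).quantize(_quantum(ndigits), rounding=ROUND_HALF_EVEN))
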