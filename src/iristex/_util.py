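"""Small shared helpers."""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at `ndigits` decimals.

    Python's built-in ``round`` uses banker's rounding; the tabulated
    percentages use conventional half-up rounding, so it is applied
    everywhere a printed-precision value is produced.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
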