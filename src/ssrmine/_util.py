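"""Small shared helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of printed report
    tables), via decimal arithmetic to avoid binary-float tie artifacts."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """100*numerator/denominator rounded half-up; exact in decimal for
    integer inputs so printed-table percentages reproduce bit-for-bit."""
    if denominator == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    q = Decimal(1).scaleb(-ndigits)
    value = Decimal(100) * Decimal(repr(numerator)) / Decimal(repr(denominator))
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]
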