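"""Small shared helpers: strand arithmetic and printed-style rounding."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero, as in printed percentages.

    Python's built-in round() is banker's rounding; depth/percentage tables
    here follow the half-up convention (e.g. 83.0985... -> 83.10).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_half_up_int(x: float) -> int:
    return int(round_half_up(x, 0))
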