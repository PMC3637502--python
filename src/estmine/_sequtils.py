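"""Shared low-level sequence helpers (DNA/RNA alphabets, complements, rounding)."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

DNA_ALPHABET = frozenset("ACGTN")
RNA_ALPHABET = frozenset("ACGUN")

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")
_RNA_COMP = str.maketrans("ACGUN", "UGCAN")


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


def dna_to_rna(seq: str) -> str:
    return seq.replace("T", "U")


def rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T")


def gc_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding, used only at report boundaries."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
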