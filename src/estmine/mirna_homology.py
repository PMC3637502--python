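"""Homology scan for known mature miRNAs in EST reads.

Conserved mature sequences are located by full-length, ungapped (Hamming)
placement on either strand of each read, allowing a small mismatch budget
(default 2, the conventional cutoff for cross-species mature conservation).
Around each match, candidate precursor windows are excised at a ladder of
flank widths so that downstream folding can discover the true stem-loop
extent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._sequtils import dna_to_rna, revcomp_dna, rna_to_dna
from .io_formats import MatureMirna, SequenceRecord

DEFAULT_FLANK_SET = (20, 40, 60, 90, 130)
#: Excised windows must exceed the mature by at least this many bases to be
#: worth folding (a stem needs a star arm and a loop).
MIN_WINDOW_EXTRA = 16


@dataclass(frozen=True)
class MatureMatch:
    """A full-length placement of a mature miRNA on a read (1-based, inclusive)."""

    read_id: str
    mirna_id: str
    read_start: int
    read_end: int
    strand: str  # '+' or '-'; '-' means the mature matches the reverse complement
    n_mismatches: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.read_start < 1 or self.read_end < self.read_start:
            raise ValueError("bad match coordinates")


@dataclass(frozen=True)
class PrecursorCandidate:
    """A precursor window around a mature match, oriented mature-sense, RNA alphabet."""

    read_id: str
    mirna_id: str
    precursor_seq: str
    mature_start: int  # 1-based within precursor_seq
    mature_end: int
    upstream_flank: int = 0
    downstream_flank: int = 0
    n_mismatches: int = 0
    strand: str = "+"

    @property
    def length(self) -> int:
        return len(self.precursor_seq)

    @property
    def mature_seq(self) -> str:
        return self.precursor_seq[self.mature_start - 1 : self.mature_end]


_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _CODE[ord(_b)] = _i
_N_CODE = 4


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def scan_matches(
    reads: Sequence[SequenceRecord],
    reference: Sequence[MatureMirna],
    max_mismatches: int = 2,
) -> list[MatureMatch]:
    """Find every near-exact mature placement on either strand of each read.

    A placement is reported when the full-length mature (transcribed to DNA)
    aligns ungapped with Hamming distance <= ``max_mismatches``; windows
    containing N are suppressed.  Output is sorted by
    (read_id, read_start, mirna_id, strand).
    """
    if not reference:
        raise ValueError("mature reference must be non-empty")
    queries = []
    for m in reference:
        fwd = rna_to_dna(m.seq)
        queries.append((m.id, fwd, revcomp_dna(fwd)))
    out: list[MatureMatch] = []
    for read in reads:
        arr = _encode(read.seq)
        if arr.size == 0:
            continue
        for mir_id, fwd, rev in queries:
            m = len(fwd)
            if arr.size < m:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(arr, m)
            has_n = (windows == _N_CODE).any(axis=1)
            for strand, q in (("+", fwd), ("-", rev)):
                mism = (windows != _encode(q)).sum(axis=1)
                ok = np.nonzero((mism <= max_mismatches) & ~has_n)[0]
                for off in ok:
                    out.append(
                        MatureMatch(
                            read_id=read.id,
                            mirna_id=mir_id,
                            read_start=int(off) + 1,
                            read_end=int(off) + m,
                            strand=strand,
                            n_mismatches=int(mism[off]),
                        )
                    )
    out.sort(key=lambda h: (h.read_id, h.read_start, h.mirna_id, h.strand))
    return out


def excise_windows(
    read: SequenceRecord,
    match: MatureMatch,
    flank_set: Sequence[int] = DEFAULT_FLANK_SET,
) -> list[PrecursorCandidate]:
    """Excise candidate precursor windows around a mature match.

    For each flank width f, up to f bases on each side of the mature are
    taken (clipped at the read ends).  Minus-strand matches are
    reverse-complemented first so the mature always appears in sense; the
    window is then converted to the RNA alphabet.  Windows shorter than
    mature + :data:`MIN_WINDOW_EXTRA` bases are dropped.
    """
    if match.read_id != read.id:
        raise ValueError(f"match read {match.read_id!r} is not read {read.id!r}")
    if match.read_end > read.length:
        raise ValueError("match lies outside the read")
    seq = read.seq
    start, end = match.read_start, match.read_end
    if match.strand == "-":
        seq = revcomp_dna(seq)
        start, end = read.length - match.read_end + 1, read.length - match.read_start + 1
    mature_len = end - start + 1
    out: list[PrecursorCandidate] = []
    for f in flank_set:
        w_start = max(1, start - f)
        w_end = min(read.length, end + f)
        if w_end - w_start + 1 < mature_len + MIN_WINDOW_EXTRA:
            continue
        window = seq[w_start - 1 : w_end]
        out.append(
            PrecursorCandidate(
                read_id=read.id,
                mirna_id=match.mirna_id,
                precursor_seq=dna_to_rna(window),
                mature_start=start - w_start + 1,
                mature_end=end - w_start + 1,
                upstream_flank=start - w_start,
                downstream_flank=w_end - end,
                n_mismatches=match.n_mismatches,
                strand=match.strand,
            )
        )
    return out
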