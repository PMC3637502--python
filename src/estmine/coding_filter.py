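"""Removal of repeat-derived and protein-coding reads from the candidate pool.

Candidate miRNA precursors must be non-coding, so reads carrying mature
matches are screened three ways, in order of precedence: an externally
supplied table of protein-homology hits, a six-frame long-ORF heuristic, and
a repeat-coverage fraction (homopolymers and microsatellites).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from ._sequtils import revcomp_dna
from .io_formats import SequenceRecord
from .mirna_homology import MatureMatch
from .ssr_scan import find_ssrs

STOP_CODONS = {"TAA", "TAG", "TGA"}
MIN_HOMOPOLYMER = 10


@dataclass(frozen=True)
class FilterDecision:
    read_id: str
    kept: bool
    reason: str  # none | coding_hit | coding_orf | repeat

    def __post_init__(self) -> None:
        if self.kept != (self.reason == "none"):
            raise ValueError("kept flag inconsistent with reason")


def _longest_orf_in_frame(seq: str, frame: int) -> int:
    """Longest ATG..stop ORF (codons incl. ATG, excl. stop) in one frame."""
    best = 0
    start: Optional[int] = None
    n_codons = 0
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            if start is not None:
                best = max(best, n_codons)
            start, n_codons = None, 0
        elif start is None and codon == "ATG":
            start, n_codons = i, 1
        elif start is not None:
            n_codons += 1
    return best


def orf_coding_score(
    seq: SequenceRecord | str, min_orf_codons: int = 100
) -> tuple[int, bool]:
    """Longest open reading frame over all six frames, and a coding call.

    An ORF runs from an ATG to the next in-frame stop; its length is counted
    in codons including the ATG and excluding the stop.  ORFs still open at
    the read end are not counted (single-pass ESTs are fragments, but an
    unterminated frame gives no stop-pattern evidence either way; the
    external hit table is the stronger signal for truncated CDS).
    """
    s = seq.seq if isinstance(seq, SequenceRecord) else seq
    longest = 0
    for strand_seq in (s, revcomp_dna(s)):
        for frame in range(3):
            longest = max(longest, _longest_orf_in_frame(strand_seq, frame))
    return longest, longest >= min_orf_codons


def repeat_fraction(seq: SequenceRecord | str) -> float:
    """Fraction of bases covered by homopolymers (>=10) or default-threshold SSRs."""
    s = seq.seq if isinstance(seq, SequenceRecord) else seq
    if not s:
        return 0.0
    rec = seq if isinstance(seq, SequenceRecord) else SequenceRecord(id="_q", seq=s)
    covered = [False] * len(s)
    for ssr in find_ssrs(rec):
        for i in range(ssr.start - 1, ssr.end):
            covered[i] = True
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        if s[i] != "N" and j - i >= MIN_HOMOPOLYMER:
            for k in range(i, j):
                covered[k] = True
        i = j
    return sum(covered) / len(s)


def filter_noncoding(
    candidates: Sequence[MatureMatch],
    reads: Mapping[str, SequenceRecord] | Sequence[SequenceRecord],
    coding_hits: Optional[Iterable[str]] = None,
    repeat_max: float = 0.5,
    min_orf_codons: int = 100,
) -> tuple[list[MatureMatch], list[FilterDecision]]:
    """Keep candidates whose carrier reads look non-coding and non-repetitive.

    Precedence per read: external homology evidence (``coding_hits``) beats
    the ORF heuristic, which beats the repeat fraction.  One decision is
    logged per candidate-bearing read.
    """
    read_map = (
        dict(reads) if isinstance(reads, Mapping) else {r.id: r for r in reads}
    )
    hits = set(coding_hits or ())
    decisions: dict[str, FilterDecision] = {}
    kept: list[MatureMatch] = []
    for cand in candidates:
        rid = cand.read_id
        if rid not in read_map:
            raise KeyError(f"candidate references unknown read {rid!r}")
        if rid not in decisions:
            if rid in hits:
                reason = "coding_hit"
            elif orf_coding_score(read_map[rid], min_orf_codons)[1]:
                reason = "coding_orf"
            elif repeat_fraction(read_map[rid]) > repeat_max:
                reason = "repeat"
            else:
                reason = "none"
            decisions[rid] = FilterDecision(rid, kept=reason == "none", reason=reason)
        if decisions[rid].kept:
            kept.append(cand)
    return kept, list(decisions.values())


def read_coding_hits(path) -> set[str]:
    """Read a one-column table of read ids with protein-homology evidence."""
    ids: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line.split("\t")[0])
    return ids
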