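"""Flanking-primer selection for SSR loci.

A reduced, deterministic Primer3-style search: exhaustive enumeration of
left/right primer placements around the repeat under hard constraints
(product 100-300 nt spanning the SSR, primer length 18-24 nt, GC 40-65%, no
N), ranked by a transparent weighted score against the optima (20 nt, 60 C
annealing, 50% GC, matched pair Tm).  Tm uses the basic long-oligo formula

    Tm = 64.9 + 41 * (GC_count - 16.4) / length.

There are no thermodynamic dimer or hairpin checks; the point is the
constraint set, and every weight is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from ._sequtils import revcomp_dna, round_half_up
from .io_formats import SequenceRecord
from .ssr_scan import SsrRecord


@dataclass(frozen=True)
class PrimerConstraints:
    product_min: int = 100
    product_max: int = 300
    primer_len_min: int = 18
    primer_len_max: int = 24
    primer_len_opt: int = 20
    tm_opt: float = 60.0
    gc_min: float = 40.0
    gc_max: float = 65.0
    gc_opt: float = 50.0
    # score weights
    w_len: float = 1.0
    w_tm: float = 1.0
    w_gc: float = 0.1
    w_tm_diff: float = 2.0

    def __post_init__(self) -> None:
        if not self.product_min <= self.product_max:
            raise ValueError("product range out of order")
        if not self.primer_len_min <= self.primer_len_opt <= self.primer_len_max:
            raise ValueError("primer length optimum outside range")
        if not self.gc_min <= self.gc_opt <= self.gc_max:
            raise ValueError("GC optimum outside range")


@dataclass(frozen=True)
class PrimerPair:
    left_seq: str
    right_seq: str  # 5'->3' on the reverse strand
    left_start: int  # 1-based position of the left primer's 5' base
    right_start: int  # 1-based position of the right primer's binding-site 5' base (forward strand)
    left_tm: float
    right_tm: float
    left_gc: float
    right_gc: float
    product_size: int
    score: float


def primer_tm(seq: str) -> float:
    """Basic long-oligo melting temperature, 2 dp, for 18-24 nt primers."""
    if not 18 <= len(seq) <= 24:
        raise ValueError(f"primer length {len(seq)} outside 18-24 nt")
    if "N" in seq:
        raise ValueError("primer contains N")
    gc = seq.count("G") + seq.count("C")
    return round_half_up(64.9 + 41 * (gc - 16.4) / len(seq), 2)


def _gc_pct(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) * 100


def validate_pair(
    unigene: SequenceRecord,
    ssr: SsrRecord,
    pair: PrimerPair,
    constraints: PrimerConstraints = PrimerConstraints(),
) -> bool:
    """Independent hard-constraint check of a returned pair (used by tests too)."""
    c = constraints
    left_end = pair.left_start + len(pair.left_seq) - 1
    right_end = pair.right_start + len(pair.right_seq) - 1
    fwd_site = unigene.seq[pair.right_start - 1 : right_end]
    return (
        1 <= pair.left_start
        and right_end <= unigene.length
        and left_end < ssr.start
        and pair.right_start > ssr.end
        and pair.product_size == right_end - pair.left_start + 1
        and c.product_min <= pair.product_size <= c.product_max
        and c.primer_len_min <= len(pair.left_seq) <= c.primer_len_max
        and c.primer_len_min <= len(pair.right_seq) <= c.primer_len_max
        and unigene.seq[pair.left_start - 1 : left_end] == pair.left_seq
        and revcomp_dna(fwd_site) == pair.right_seq
        and "N" not in pair.left_seq
        and "N" not in pair.right_seq
        and c.gc_min <= _gc_pct(pair.left_seq) <= c.gc_max
        and c.gc_min <= _gc_pct(pair.right_seq) <= c.gc_max
    )


def _candidate_primers(
    seq: str, lo: int, hi: int, constraints: PrimerConstraints
) -> list[tuple[int, int, float, float]]:
    """Feasible (start0, length, gc%, tm) primers fully inside seq[lo:hi] (0-based)."""
    c = constraints
    out = []
    # prefix GC counts for O(1) windows
    gc_cum = [0]
    for b in seq:
        gc_cum.append(gc_cum[-1] + (b in "GC"))
    n_cum = [0]
    for b in seq:
        n_cum.append(n_cum[-1] + (b == "N"))
    for start in range(lo, hi):
        for length in range(c.primer_len_min, c.primer_len_max + 1):
            end = start + length
            if end > hi:
                break
            if n_cum[end] - n_cum[start]:
                continue
            gc_count = gc_cum[end] - gc_cum[start]
            gc = gc_count / length * 100
            if not c.gc_min <= gc <= c.gc_max:
                continue
            tm = 64.9 + 41 * (gc_count - 16.4) / length
            out.append((start, length, gc, tm))
    return out


def design_primers(
    unigene: SequenceRecord,
    ssr: SsrRecord,
    constraints: PrimerConstraints = PrimerConstraints(),
) -> Optional[PrimerPair]:
    """Best-scoring feasible primer pair flanking an SSR, or None.

    Score = sum over both primers of w_len*|len-opt| + w_tm*|Tm-opt| +
    w_gc*|GC-opt|, plus w_tm_diff*|Tm_left - Tm_right|.  Ties break toward
    the smaller product, then the leftmost placement.  Deterministic.
    """
    if ssr.unigene_id != unigene.id or ssr.end > unigene.length or ssr.start < 1:
        raise ValueError("SSR does not lie within the unigene")
    c = constraints
    seq = unigene.seq
    ssr_lo = ssr.start - 1  # 0-based first repeat base
    ssr_hi = ssr.end  # 0-based exclusive
    lefts = _candidate_primers(
        seq, max(0, ssr_hi - c.product_max), ssr_lo, constraints
    )
    rights = _candidate_primers(
        seq, ssr_hi, min(len(seq), ssr_lo + c.product_max), constraints
    )
    if not lefts or not rights:
        return None

    def part_score(length: int, gc: float, tm: float) -> float:
        return (
            c.w_len * abs(length - c.primer_len_opt)
            + c.w_tm * abs(tm - c.tm_opt)
            + c.w_gc * abs(gc - c.gc_opt)
        )

    best_key = None
    best = None
    for ls, ll, lgc, ltm in lefts:
        l_part = part_score(ll, lgc, ltm)
        for rs, rl, rgc, rtm in rights:
            product = (rs + rl) - ls
            if product < c.product_min:
                continue
            if product > c.product_max:
                continue
            score = l_part + part_score(rl, rgc, rtm) + c.w_tm_diff * abs(ltm - rtm)
            key = (score, product, ls, rs, ll, rl)
            if best_key is None or key < best_key:
                best_key = key
                best = (ls, ll, lgc, ltm, rs, rl, rgc, rtm, product, score)
    if best is None:
        return None
    ls, ll, lgc, ltm, rs, rl, rgc, rtm, product, score = best
    return PrimerPair(
        left_seq=seq[ls : ls + ll],
        right_seq=revcomp_dna(seq[rs : rs + rl]),
        left_start=ls + 1,
        right_start=rs + 1,
        left_tm=round_half_up(ltm, 2),
        right_tm=round_half_up(rtm, 2),
        left_gc=round_half_up(lgc, 1),
        right_gc=round_half_up(rgc, 1),
        product_size=product,
        score=score,
    )
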