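"""MISA-equivalent detection of perfect microsatellites (SSRs) in unigenes.

A perfect SSR is a maximal tandem run of a primitive 2-6 nt motif meeting a
per-motif-length minimum repeat number (defaults 6/5/4/4/4 for di- through
hexa-nucleotides, the usual EST-SSR screening parameters).  Motif classes
collapse rotations and reverse complements ("AG/CT"), and the summary mirrors
the conventional motif-length x repeat-number count matrix, per-unigene
tallies and density per Mb.

Dialect notes: only perfect runs are reported (interrupted/compound repeats
count as their component perfect runs) and mononucleotide runs are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from ._sequtils import revcomp_dna, round_half_up
from .io_formats import SequenceRecord

DEFAULT_THRESHOLDS: Mapping[int, int] = {2: 6, 3: 5, 4: 4, 5: 4, 6: 4}
REPEAT_BINS = ("4", "5", "6", "7", "8", "9", "10", ">10")


@dataclass(frozen=True)
class SsrRecord:
    """One perfect SSR: motif as found, repeat count and 1-based inclusive span."""

    unigene_id: str
    motif: str
    n_repeats: int
    start: int
    end: int
    ssr_index: int = 1

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.motif) * self.n_repeats:
            raise ValueError("SSR span inconsistent with motif length x repeats")

    @property
    def motif_class(self) -> str:
        return motif_class(self.motif)


def is_primitive(motif: str) -> bool:
    """True when the motif is not a whole-number power of a shorter string."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def motif_class(motif: str) -> str:
    """Canonical strand- and rotation-invariant label, e.g. 'AG/CT'.

    The label's left side is the lexicographically smallest rotation over
    both the motif and its reverse complement; the right side is the smallest
    rotation of the opposite strand's motif.
    """
    if not 2 <= len(motif) <= 6:
        raise ValueError(f"motif length {len(motif)} outside 2-6")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    rots = {motif[i:] + motif[:i] for i in range(len(motif))}
    rc = revcomp_dna(motif)
    rc_rots = {rc[i:] + rc[:i] for i in range(len(rc))}
    fwd_min, rc_min = min(rots), min(rc_rots)
    if fwd_min <= rc_min:
        return f"{fwd_min}/{rc_min}"
    return f"{rc_min}/{fwd_min}"


def find_ssrs(
    seq: SequenceRecord,
    thresholds: Mapping[int, int] = DEFAULT_THRESHOLDS,
) -> list[SsrRecord]:
    """All maximal perfect tandem repeats meeting the repeat-number thresholds.

    Each run is attributed to its primitive motif at the leftmost position of
    the maximal run ((AT)x6, never (ATAT)x3 or a mid-run start); runs
    containing N are excluded; partial trailing motif copies do not count
    toward the repeat number.  Records are sorted by start coordinate.
    """
    s = seq.seq
    L = len(s)
    found: list[SsrRecord] = []
    for i in range(L - 3):
        for k in sorted(thresholds):
            if i + 2 * k > L:
                break
            motif = s[i : i + k]
            if "N" in motif or not is_primitive(motif):
                continue
            # leftmost start of a maximal period-k run
            if i > 0 and s[i - 1] == s[i + k - 1]:
                continue
            j = i + k
            while j + k <= L and s[j : j + k] == motif:
                j += k
            n = (j - i) // k
            if n >= thresholds[k]:
                found.append(
                    SsrRecord(
                        unigene_id=seq.id,
                        motif=motif,
                        n_repeats=n,
                        start=i + 1,
                        end=i + k * n,
                    )
                )
    found.sort(key=lambda r: (r.start, len(r.motif)))
    return [
        SsrRecord(r.unigene_id, r.motif, r.n_repeats, r.start, r.end, ssr_index=ix)
        for ix, r in enumerate(found, start=1)
    ]


def scan_collection(
    unigenes: Sequence[SequenceRecord],
    thresholds: Mapping[int, int] = DEFAULT_THRESHOLDS,
) -> list[SsrRecord]:
    out: list[SsrRecord] = []
    for u in unigenes:
        out.extend(find_ssrs(u, thresholds))
    return out


@dataclass(frozen=True)
class SsrSummary:
    """Collection-level SSR statistics (counts matrix, density, class frequencies)."""

    matrix: pd.DataFrame  # index: motif length 2-6; columns: repeat-number bins
    n_ssrs: int
    n_unigenes_with_ssr: int
    n_unigenes_with_2plus: int
    total_bases: int
    density_per_mb: float
    motif_class_frequencies: dict[str, float] = field(default_factory=dict)

    def row_totals(self) -> pd.Series:
        return self.matrix.sum(axis=1)

    def column_totals(self) -> pd.Series:
        return self.matrix.sum(axis=0)

    def row_percentages(self) -> pd.Series:
        return (self.row_totals() / self.n_ssrs * 100).map(lambda v: round_half_up(v, 1))

    def column_percentages(self) -> pd.Series:
        return (self.column_totals() / self.n_ssrs * 100).map(
            lambda v: round_half_up(v, 1)
        )


def _repeat_bin(n: int) -> str:
    return str(n) if n <= 10 else ">10"


def ssr_density(n_ssrs: int, total_bases: int) -> float:
    """SSR density in repeats per Mb, reported at 1 decimal place."""
    if total_bases <= 0:
        raise ValueError("total_bases must be positive")
    return round_half_up(n_ssrs / (total_bases / 1e6), 1)


def summarize_ssrs(
    records: Sequence[SsrRecord], unigenes: Sequence[SequenceRecord]
) -> SsrSummary:
    """Tally SSR records into the motif-length x repeat-number matrix and density."""
    known = {u.id: u.length for u in unigenes}
    matrix = pd.DataFrame(
        0, index=pd.Index(range(2, 7), name="motif_len"), columns=list(REPEAT_BINS)
    )
    per_unigene: dict[str, int] = {}
    class_counts: dict[str, int] = {}
    for rec in records:
        if rec.unigene_id not in known:
            raise KeyError(f"SSR record references unknown unigene {rec.unigene_id!r}")
        matrix.loc[len(rec.motif), _repeat_bin(rec.n_repeats)] += 1
        per_unigene[rec.unigene_id] = per_unigene.get(rec.unigene_id, 0) + 1
        cls = rec.motif_class
        class_counts[cls] = class_counts.get(cls, 0) + 1
    n = len(records)
    total_bases = sum(known.values())
    freqs = (
        {c: round_half_up(v / n * 100, 1) for c, v in sorted(class_counts.items())}
        if n
        else {}
    )
    return SsrSummary(
        matrix=matrix,
        n_ssrs=n,
        n_unigenes_with_ssr=len(per_unigene),
        n_unigenes_with_2plus=sum(1 for v in per_unigene.values() if v >= 2),
        total_bases=total_bases,
        density_per_mb=ssr_density(n, total_bases) if total_bases else 0.0,
        motif_class_frequencies=freqs,
    )
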