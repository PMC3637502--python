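"""Collection-level summaries: length statistics and the four-set Venn partition.

`length_summary` gives the totals usually printed for an assembly (count,
bases, mean/min/max length, percent of sequences over 400 bp).
`venn_partition` assigns each unigene id to exactly one of the 15 non-empty
membership regions of four labeled sets (e.g. root/stem/leaf/flower);
"private to X" means the singleton region of X, not X's marginal total.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from ._sequtils import round_half_up
from .io_formats import SequenceRecord


@dataclass(frozen=True)
class LengthSummary:
    n_seqs: int
    n_bases: int
    mean_len: float  # 1 dp
    min_len: int
    max_len: int
    frac_over_400: float  # percent, 1 dp

    def __post_init__(self) -> None:
        if not self.min_len <= self.mean_len <= self.max_len:
            raise ValueError("min <= mean <= max violated")


def length_summary(records: Sequence[SequenceRecord]) -> LengthSummary:
    if not records:
        raise ValueError("cannot summarize an empty collection")
    lengths = [r.length for r in records]
    n = len(lengths)
    return LengthSummary(
        n_seqs=n,
        n_bases=sum(lengths),
        mean_len=round_half_up(sum(lengths) / n, 1),
        min_len=min(lengths),
        max_len=max(lengths),
        frac_over_400=round_half_up(sum(1 for l in lengths if l > 400) / n * 100, 1),
    )


def venn_partition(sets: Mapping[str, Iterable[str]]) -> dict[frozenset[str], int]:
    """Counts for all 15 non-empty membership regions of four labeled sets.

    Keys are frozensets of the labels an id belongs to; every region is
    present in the result (zero when empty), and each id contributes to
    exactly one region.
    """
    if len(sets) != 4:
        raise ValueError(f"expected exactly 4 labeled sets, got {len(sets)}")
    labels = list(sets)
    as_sets = {lab: set(ids) for lab, ids in sets.items()}
    regions: dict[frozenset[str], int] = {
        frozenset(combo): 0
        for r in range(1, 5)
        for combo in combinations(labels, r)
    }
    for uid in set().union(*as_sets.values()):
        member = frozenset(lab for lab in labels if uid in as_sets[lab])
        regions[member] += 1
    return regions


def venn_table(partition: Mapping[frozenset[str], int]) -> list[tuple[str, int]]:
    """Stable text rendering of a partition, largest membership first."""
    rows = sorted(
        partition.items(), key=lambda kv: (-len(kv[0]), tuple(sorted(kv[0])))
    )
    return [("+".join(sorted(k)), v) for k, v in rows]
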