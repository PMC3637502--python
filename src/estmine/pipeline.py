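"""End-to-end miRNA discovery: scan -> noncoding filter -> excise -> hairpin call."""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .coding_filter import FilterDecision, filter_noncoding
from .hairpin_eval import FoldingEngine, MirnaRecord, call_mirna
from .io_formats import MatureMirna, SequenceRecord
from .mirna_homology import (
    DEFAULT_FLANK_SET,
    MatureMatch,
    excise_windows,
    scan_matches,
)


def discover_mirnas(
    reads: Sequence[SequenceRecord],
    reference: Sequence[MatureMirna],
    engine: FoldingEngine,
    max_mismatches: int = 2,
    flank_set: Sequence[int] = DEFAULT_FLANK_SET,
    coding_hits: Optional[Iterable[str]] = None,
    repeat_max: float = 0.5,
    mfei_min: float = 0.85,
    name_prefix: str = "cand",
) -> tuple[list[MirnaRecord], list[MatureMatch], list[FilterDecision]]:
    """Run the homology -> filtering -> hairpin/MFEI route over a collection.

    Returns the accepted miRNA records together with the raw mature matches
    and the per-read filter decisions, so callers can report attrition at
    each stage.
    """
    matches = scan_matches(reads, reference, max_mismatches=max_mismatches)
    kept, decisions = filter_noncoding(
        matches, reads, coding_hits=coding_hits, repeat_max=repeat_max
    )
    read_map = {r.id: r for r in reads}
    candidates = []
    for match in kept:
        candidates.extend(excise_windows(read_map[match.read_id], match, flank_set))
    records = call_mirna(
        candidates, engine, mfei_min=mfei_min, name_prefix=name_prefix
    )
    return records, matches, decisions
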