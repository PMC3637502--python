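"""Read quality control: adapter trimming and minimum-length filtering.

Trimming removes the longest terminal (prefix/suffix) adapter overlap,
ungapped, allowing a configurable mismatch rate; interior adapter copies are
deliberately untouched.  Length filtering is strict: reads *shorter than*
the cutoff are removed, so a read of exactly the cutoff length survives.
Trimming runs before filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .io_formats import SequenceRecord

MIN_ADAPTER_OVERLAP = 8


@dataclass(frozen=True)
class QcReport:
    n_input: int
    n_trimmed: int
    n_removed_short: int
    n_kept: int
    min_len: int

    def __post_init__(self) -> None:
        if min(self.n_input, self.n_trimmed, self.n_removed_short, self.n_kept) < 0:
            raise ValueError("QC counts must be non-negative")
        if self.n_kept != self.n_input - self.n_removed_short:
            raise ValueError("inconsistent QC report: kept != input - removed")


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _best_prefix_trim(seq: str, adapters: Sequence[str], rate: float) -> int:
    """Longest L such that some adapter's 3' suffix of length L matches seq[:L]."""
    best = 0
    for ad in adapters:
        top = min(len(seq), len(ad))
        for length in range(top, max(best, MIN_ADAPTER_OVERLAP - 1), -1):
            if _mismatches(ad[-length:], seq[:length]) <= int(rate * length):
                best = max(best, length)
                break
    return best


def _best_suffix_trim(seq: str, adapters: Sequence[str], rate: float) -> int:
    """Longest L such that some adapter's 5' prefix of length L matches seq[-L:]."""
    best = 0
    for ad in adapters:
        top = min(len(seq), len(ad))
        for length in range(top, max(best, MIN_ADAPTER_OVERLAP - 1), -1):
            if _mismatches(ad[:length], seq[-length:]) <= int(rate * length):
                best = max(best, length)
                break
    return best


def trim_adapters(
    read: SequenceRecord,
    adapters: Sequence[str],
    max_mismatch_rate: float = 0.1,
) -> SequenceRecord:
    """Trim terminal adapter matches off both ends of a read.

    An adapter may run off the 5' end of the read (its suffix matching the
    read prefix) or off the 3' end (its prefix matching the read suffix); at
    least :data:`MIN_ADAPTER_OVERLAP` overlapping bases are required, with at
    most ``floor(rate * overlap)`` mismatches.  The longest qualifying
    overlap per end, over all adapters, is removed.  No-op when nothing
    matches.
    """
    if not adapters:
        raise ValueError("adapter list must be non-empty")
    ads = [a.upper() for a in adapters]
    for a in ads:
        if len(a) < MIN_ADAPTER_OVERLAP:
            raise ValueError(f"adapter {a!r} shorter than {MIN_ADAPTER_OVERLAP} bases")
    left = _best_prefix_trim(read.seq, ads, max_mismatch_rate)
    remainder = read.seq[left:]
    right = _best_suffix_trim(remainder, ads, max_mismatch_rate)
    trimmed = remainder[: len(remainder) - right] if right else remainder
    if trimmed == read.seq:
        return read
    return replace(read, seq=trimmed)


def filter_short(
    reads: Sequence[SequenceRecord], min_len: int = 50
) -> tuple[list[SequenceRecord], QcReport]:
    """Drop reads shorter than ``min_len`` bases, preserving input order."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = [r for r in reads if r.length >= min_len]
    report = QcReport(
        n_input=len(reads),
        n_trimmed=0,
        n_removed_short=len(reads) - len(kept),
        n_kept=len(kept),
        min_len=min_len,
    )
    return kept, report


def run_qc(
    reads: Sequence[SequenceRecord],
    adapters: Sequence[str] | None = None,
    min_len: int = 50,
    max_mismatch_rate: float = 0.1,
) -> tuple[list[SequenceRecord], QcReport]:
    """Adapter trimming (when adapters are supplied) followed by length filtering."""
    n_trimmed = 0
    processed: list[SequenceRecord] = []
    for read in reads:
        if adapters:
            out = trim_adapters(read, adapters, max_mismatch_rate)
            if out.seq != read.seq:
                n_trimmed += 1
            processed.append(out)
        else:
            processed.append(read)
    kept, report = filter_short(processed, min_len)
    return kept, replace(report, n_trimmed=n_trimmed)
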