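"""Hairpin screening of candidate precursors and the MFEI filter.

Candidate windows are folded by a pluggable engine (ViennaRNA when its
bindings are importable, or precomputed fixtures), checked for a stem-loop
topology with the mature on a single arm, and scored with the minimal
folding free energy index

    MFEI = AMFE / GC%,   AMFE = |MFE| / precursor_length * 100,

where GC% is the precursor's G+C content expressed as a percentage *number*
(e.g. 38, not 0.38).  Precursors with MFEI >= 0.85 (inclusive) pass: this is
the conventional empirical boundary separating miRNA precursors from other
noncoding and coding RNAs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Protocol, Sequence

from ._sequtils import gc_fraction, round_half_up
from .io_formats import StructureFixture
from .mirna_homology import PrecursorCandidate

MFEI_DEFAULT_MIN = 0.85


class FoldingEngine(Protocol):
    """Anything that maps an RNA sequence to (dot-bracket, MFE kcal/mol <= 0)."""

    def fold(self, seq: str) -> tuple[str, float]:  # pragma: no cover - protocol
        ...


class ViennaEngine:
    """Thermodynamic folding through the ViennaRNA bindings."""

    def __init__(self) -> None:
        try:
            import RNA
        except ImportError as exc:  # pragma: no cover - environment dependent
            raise ImportError(
                "ViennaRNA python bindings are not installed; "
                "use a fixture engine or install ViennaRNA"
            ) from exc
        self._rna = RNA

    def fold(self, seq: str) -> tuple[str, float]:
        structure, mfe = self._rna.fold(seq)
        return structure, float(mfe)


class FixtureEngine:
    """Folding-free engine backed by precomputed (sequence -> structure) fixtures."""

    def __init__(self, table: Mapping[str, tuple[str, float]]) -> None:
        self._table = dict(table)

    @classmethod
    def from_fixtures(
        cls,
        fixtures: Iterable[StructureFixture],
        sequences: Mapping[str, str],
    ) -> "FixtureEngine":
        """Build from fixtures keyed by id plus an id -> RNA sequence map."""
        table = {}
        for fx in fixtures:
            if fx.id not in sequences:
                raise KeyError(f"no sequence for fixture {fx.id!r}")
            seq = sequences[fx.id]
            if len(seq) != len(fx.structure):
                raise ValueError(f"fixture {fx.id!r}: structure/sequence length mismatch")
            table[seq] = (fx.structure, fx.mfe)
        return cls(table)

    def fold(self, seq: str) -> tuple[str, float]:
        try:
            return self._table[seq]
        except KeyError:
            raise KeyError(
                f"no precomputed structure for sequence of length {len(seq)} "
                f"starting {seq[:12]!r}"
            ) from None


def get_engine(name: str = "vienna") -> FoldingEngine:
    if name == "vienna":
        return ViennaEngine()
    raise ValueError(f"unknown folding engine {name!r}")


@dataclass(frozen=True)
class HairpinAssessment:
    is_hairpin: bool
    arm: str  # 5p | 3p | spanning
    mature_star_mismatches: int
    mature_unpaired: int
    multiloop_in_mature: bool


@dataclass(frozen=True)
class MirnaRecord:
    """One accepted miRNA candidate with its precursor statistics."""

    name: str
    query_mirna: str
    mature_len: int
    mature_seq: str
    n_mismatches_to_query: int
    arm: str
    gc_percent: float
    precursor_len: int
    mfe_abs: float
    mfei: float
    source_read: str

    def __post_init__(self) -> None:
        if not 19 <= self.mature_len <= 25:
            raise ValueError(f"{self.name}: mature length {self.mature_len} out of range")
        expect = (self.mfe_abs / self.precursor_len * 100) / self.gc_percent
        if abs(self.mfei - expect) >= 0.005:
            raise ValueError(f"{self.name}: MFEI inconsistent with MFE/PL/GC%")


def gc_percent(seq: str) -> float:
    """G+C content as a percentage number (0-100)."""
    return gc_fraction(seq) * 100


def amfe(mfe: float, length: int) -> float:
    """Adjusted MFE: |MFE| per 100 nt."""
    if length <= 0:
        raise ValueError("length must be positive")
    return abs(mfe) / length * 100


def mfei(mfe: float, length: int, gc: float) -> float:
    """Minimal folding free energy index, AMFE divided by GC percentage."""
    if gc <= 0:
        raise ValueError("GC percentage must be positive")
    return amfe(mfe, length) / gc


def pair_table(structure: str) -> list[int]:
    """0-based partner index per position, -1 for unpaired; errors on imbalance."""
    partners = [-1] * len(structure)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket structure")
            j = stack.pop()
            partners[i], partners[j] = j, i
        elif ch != ".":
            raise ValueError(f"illegal structure character {ch!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return partners


def assess_hairpin(
    candidate: PrecursorCandidate,
    structure: str,
    max_star_mismatches: int = 6,
    max_mature_unpaired: int = 6,
) -> HairpinAssessment:
    """Decide whether a folded window is a proper stem-loop with the mature on one arm.

    Arm assignment: 5p when every paired mature base pairs downstream of the
    mature span, 3p when upstream; mixed directions, pairing within the
    mature itself (a local hairpin, i.e. the mature contains a terminal
    loop), or a fully unpaired mature all yield 'spanning'.  Unpaired mature
    bases interior to the mature's paired stretch are counted as mature/star
    mismatches (bulges and internal loops).
    """
    if len(structure) != candidate.length:
        raise ValueError(
            f"{candidate.read_id}: structure length {len(structure)} != "
            f"precursor length {candidate.length}"
        )
    partners = pair_table(structure)
    lo, hi = candidate.mature_start - 1, candidate.mature_end - 1  # 0-based inclusive
    paired_pos = [i for i in range(lo, hi + 1) if partners[i] >= 0]
    multiloop = any(lo <= partners[i] <= hi for i in paired_pos)
    downstream = any(partners[i] > hi for i in paired_pos)
    upstream = any(partners[i] < lo for i in paired_pos)
    if not paired_pos or multiloop or (downstream and upstream):
        arm = "spanning"
    elif downstream:
        arm = "5p"
    else:
        arm = "3p"
    unpaired = (hi - lo + 1) - len(paired_pos)
    if paired_pos:
        first, last = paired_pos[0], paired_pos[-1]
        star_mm = sum(1 for i in range(first, last + 1) if partners[i] < 0)
    else:
        star_mm = hi - lo + 1
    is_hairpin = (
        arm != "spanning"
        and unpaired <= max_mature_unpaired
        and star_mm <= max_star_mismatches
        and not multiloop
    )
    return HairpinAssessment(
        is_hairpin=is_hairpin,
        arm=arm,
        mature_star_mismatches=star_mm,
        mature_unpaired=unpaired,
        multiloop_in_mature=multiloop,
    )


def mirna_family(mirna_id: str) -> str:
    """Family key of a miRBase-style name: strip the 3-letter species prefix."""
    head, _, rest = mirna_id.partition("-")
    return rest if rest and len(head) == 3 and head.isalpha() else mirna_id


def call_mirna(
    candidates: Sequence[PrecursorCandidate],
    engine: FoldingEngine,
    mfei_min: float = MFEI_DEFAULT_MIN,
    max_star_mismatches: int = 6,
    max_mature_unpaired: int = 6,
    name_prefix: str = "cand",
) -> list[MirnaRecord]:
    """Fold, assess and rank candidate windows; emit one record per (read, family).

    For every read x query-miRNA family, each excised window is folded and
    assessed; among windows that form a proper hairpin the one with the
    greatest MFEI is retained (ties: shortest precursor, then lowest mature
    start).  Records with MFEI below ``mfei_min`` are discarded; the
    threshold is inclusive.  Output order is deterministic and independent
    of candidate input order.
    """
    groups: dict[tuple[str, str], list[PrecursorCandidate]] = {}
    for cand in candidates:
        groups.setdefault((cand.read_id, mirna_family(cand.mirna_id)), []).append(cand)
    records: list[MirnaRecord] = []
    for (read_id, family), cands in sorted(groups.items()):
        best: tuple | None = None
        for cand in cands:
            try:
                structure, mfe = engine.fold(cand.precursor_seq)
            except KeyError as exc:
                raise KeyError(
                    f"no structure available for candidate {cand.mirna_id} "
                    f"on read {read_id}: {exc}"
                ) from None
            assessment = assess_hairpin(
                cand, structure, max_star_mismatches, max_mature_unpaired
            )
            if not assessment.is_hairpin:
                continue
            gc = gc_percent(cand.precursor_seq)
            score = mfei(mfe, cand.length, gc)
            key = (-score, cand.length, cand.mature_start)
            if best is None or key < best[0]:
                best = (key, cand, assessment, gc, mfe, score)
        if best is None:
            continue
        _, cand, assessment, gc, mfe, score = best
        # inclusive threshold; the epsilon keeps an exact-boundary MFEI from
        # being lost to float round-trip error
        if score < mfei_min - 1e-9:
            continue
        records.append(
            MirnaRecord(
                name=f"{name_prefix}-{family}",
                query_mirna=cand.mirna_id,
                mature_len=cand.mature_end - cand.mature_start + 1,
                mature_seq=cand.mature_seq,
                n_mismatches_to_query=cand.n_mismatches,
                arm=assessment.arm,
                gc_percent=gc,
                precursor_len=cand.length,
                mfe_abs=abs(mfe),
                mfei=score,
                source_read=read_id,
            )
        )
    return records


def records_to_table(records: Sequence[MirnaRecord]):
    """Render records in the conventional candidate-table column order."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "miRNA": r.name,
                "query": r.query_mirna,
                "ML": r.mature_len,
                "mature_seq": r.mature_seq,
                "NM": r.n_mismatches_to_query,
                "arm": r.arm,
                "GC%": round_half_up(r.gc_percent, 1),
                "PL": r.precursor_len,
                "MFE": round_half_up(r.mfe_abs, 1),
                "MFEI": round_half_up(r.mfei, 2),
                "EST_ID": r.source_read,
            }
            for r in records
        ]
    )
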