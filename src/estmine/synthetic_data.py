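"""Deterministic synthetic EST collections with planted ground truth.

The generator emulates the read material a 454-style EST survey feeds into
miRNA/SSR mining: background cDNA fragments of 50-700 bp at a configurable
GC content, plus planted features with exactly known coordinates --

* miRNA precursors built as genuine extended stem-loops (mature + star +
  terminal loop, flanked by a complementary pair so the stem continues past
  the mature duplex, as in real pre-miRNAs);
* protein-coding reads carrying a single long ORF (ATG .. stop);
* unigenes with a near-complementary miRNA target site of a chosen penalty;
* perfect SSRs of known motif and repeat number.

Every planted feature is emitted once into a truth table, and hairpins come
with a structure fixture under a stub energy model (-2 kcal/mol per paired
base) so hairpin topology and MFEI arithmetic can be tested bit-exactly
without a thermodynamic engine.  Features never overlap: each planting gets
its own carrier read.  All randomness flows from one integer seed through
numpy's PCG64, so a fixed seed reproduces the collection byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._sequtils import revcomp_dna, rna_to_dna
from .io_formats import MatureMirna, SequenceRecord, StructureFixture
from .target_prediction import score_site

_BASES = np.array(list("ACGT"))

TRUTH_COLUMNS = ("read_id", "feature_kind", "feature_id", "start", "end", "strand", "payload")


@dataclass(frozen=True)
class HairpinSpec:
    mature: MatureMirna
    n_copies: int = 1
    star_mismatches: int = 0
    loop_len: int = 12
    flank_len: int = 15
    arm: str = "5p"


@dataclass(frozen=True)
class SsrSpec:
    motif: str
    repeat_count: int
    n_copies: int = 1


@dataclass(frozen=True)
class TargetSpec:
    mature: MatureMirna
    penalty_budget: float = 0.0
    n_copies: int = 1


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_background: int = 500
    length_range: tuple[int, int] = (50, 700)
    gc_background: float = 0.45
    planted_mirnas: tuple[HairpinSpec, ...] = ()
    planted_ssrs: tuple[SsrSpec, ...] = ()
    planted_targets: tuple[TargetSpec, ...] = ()
    planted_coding: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 50 or hi < lo:
            raise ValueError("length_range minimum must be >= 50 and ordered")
        if not 0.0 <= self.gc_background <= 1.0:
            raise ValueError("gc_background must be a fraction in [0, 1]")
        for spec in self.planted_ssrs:
            if not 2 <= len(spec.motif) <= 6:
                raise ValueError(f"SSR motif {spec.motif!r} length outside 2-6")


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def make_hairpin(
    mature: MatureMirna,
    star_mismatches: int = 0,
    loop_len: int = 12,
    flank_len: int = 15,
    arm: str = "5p",
    seed: int = 0,
) -> tuple[SequenceRecord, StructureFixture, tuple[int, int]]:
    """Construct a planted pre-miRNA read with its stub-energy structure.

    Layout (5p arm): [flank][mature][loop][star][flank'], where star is the
    reverse complement of the mature carrying ``star_mismatches``
    substitutions at non-terminal positions and flank' is the reverse
    complement of flank, extending the stem.  For the 3p arm the star comes
    first.  The fixture pairs mature against star outside mismatched
    positions and the flanks against each other; its MFE is -2.0 kcal/mol
    per paired base (stub energy model).  Returns the read (DNA), the
    fixture and the mature's 1-based span within the read.
    """
    if arm not in ("5p", "3p"):
        raise ValueError(f"arm must be 5p or 3p, got {arm!r}")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    if star_mismatches > 6:
        raise ValueError("star_mismatches must be <= 6")
    if "N" in mature.seq:
        raise ValueError("mature sequence must not contain N")
    rng = np.random.default_rng(seed)
    m_dna = rna_to_dna(mature.seq)
    L = len(m_dna)
    star = list(revcomp_dna(m_dna))
    # substitutions at non-terminal star positions; each breaks one pair
    mm_star_pos = sorted(
        rng.choice(np.arange(1, L - 1), size=star_mismatches, replace=False)
    ) if star_mismatches else []
    for p in mm_star_pos:
        alternatives = [b for b in "ACGT" if b != star[p]]
        star[p] = alternatives[rng.integers(0, 3)]
    star_seq = "".join(star)
    flank5 = _random_seq(rng, flank_len, 0.5)
    flank3 = revcomp_dna(flank5)
    loop = _random_seq(rng, loop_len, 0.5)
    # mature position paired with star position L-1-i unless that star base mutated
    broken_mature = {L - 1 - p for p in mm_star_pos}
    m_struct = "".join("." if i in broken_mature else "(" for i in range(L))
    s_struct = "".join("." if p in mm_star_pos else ")" for p in range(L))
    if arm == "5p":
        seq = flank5 + m_dna + loop + star_seq + flank3
        structure = (
            "(" * flank_len + m_struct + "." * loop_len + s_struct + ")" * flank_len
        )
        span = (flank_len + 1, flank_len + L)
    else:
        # on the 3p arm the star leads; its pairing symbols open, the mature's close
        seq = flank5 + star_seq + loop + m_dna + flank3
        structure = (
            "(" * flank_len
            + s_struct.replace(")", "(")
            + "." * loop_len
            + m_struct.replace("(", ")")
            + ")" * flank_len
        )
        span = (flank_len + L + loop_len + 1, flank_len + L + loop_len + L)
    n_pairs = structure.count("(")
    read = SequenceRecord(id=f"hp-{mature.id}-s{seed}", seq=seq)
    fixture = StructureFixture(id=read.id, structure=structure, mfe=-2.0 * n_pairs)
    return read, fixture, span


def make_target_unigene(
    mature: MatureMirna,
    penalty_budget: float = 0.0,
    context_len: int = 80,
    seed: int = 0,
) -> tuple[SequenceRecord, tuple[int, int]]:
    """A unigene carrying one near-complementary target site of known penalty.

    The site starts as the exact reverse complement of the mature and is
    edited with G:U wobbles (0.5 each) and mismatches (1.0 each) until the
    recorded penalty equals ``penalty_budget``; budgets must be non-negative
    multiples of 0.5, and a half-unit component requires a G or U in the
    mature (only those bases admit a wobble).  Returns the unigene and the
    site's 1-based span.
    """
    if penalty_budget < 0:
        raise ValueError("penalty_budget must be >= 0")
    n_half = round(penalty_budget * 2)
    if abs(penalty_budget * 2 - n_half) > 1e-9:
        raise ValueError("penalty_budget must be a multiple of 0.5")
    rng = np.random.default_rng(seed)
    m = mature.seq
    L = len(m)
    n_wobble = n_half % 2
    n_mismatch = (n_half - n_wobble) // 2
    if n_wobble + n_mismatch > L:
        raise ValueError("budget unreachable: more edits than mature positions")
    wobble_ok = [i for i, b in enumerate(m) if b in "GU"]
    if n_wobble > len(wobble_ok):
        raise ValueError("budget unreachable: no G/U position available for a wobble")
    site = list(rna_to_dna(revcomp_dna(rna_to_dna(m))))  # exact complement, DNA
    chosen_w = (
        [int(rng.choice(wobble_ok))] if n_wobble else []
    )
    remaining = [i for i in range(L) if i not in chosen_w]
    chosen_m = sorted(
        int(i) for i in rng.choice(remaining, size=n_mismatch, replace=False)
    ) if n_mismatch else []
    for i in chosen_w:
        # G:U wobble: mature G faces site U(T); mature U faces site G
        site[L - 1 - i] = "T" if m[i] == "G" else "G"
    for i in chosen_m:
        forbidden = {revcomp_dna(rna_to_dna(m[i]))}
        if m[i] == "G":
            forbidden.add("T")
        elif m[i] == "U":
            forbidden.add("G")
        options = [b for b in "ACGT" if b not in forbidden]
        site[L - 1 - i] = options[rng.integers(0, len(options))]
    site_seq = "".join(site)
    achieved = score_site(mature, site_seq)
    if abs(achieved - penalty_budget) > 1e-9:  # pragma: no cover - construction guard
        raise AssertionError("constructed site penalty does not meet the budget")
    ctx1 = _random_seq(rng, context_len, 0.5)
    ctx2 = _random_seq(rng, context_len, 0.5)
    uni = SequenceRecord(id=f"tgt-{mature.id}-s{seed}", seq=ctx1 + site_seq + ctx2)
    return uni, (context_len + 1, context_len + L)


_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


def _make_coding_read(rng: np.random.Generator, n_codons: int) -> tuple[str, int, int]:
    """A read with a single ORF of ``n_codons`` codons (incl. ATG); returns span."""
    codons = ["ATG"] + [
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 1)
    ]
    orf = "".join(codons) + _STOPS[rng.integers(0, 3)]
    lead = _random_seq(rng, int(rng.integers(5, 30)), 0.5)
    tail = _random_seq(rng, int(rng.integers(5, 30)), 0.5)
    start = len(lead) + 1
    return lead + orf + tail, start, start + len(orf) - 1


def _embed_ssr(rng: np.random.Generator, motif: str, n_rep: int, read_len: int) -> tuple[str, int]:
    """Embed a perfect SSR run so its maximal-run boundaries are exactly as planted."""
    from .ssr_scan import find_ssrs

    run = motif * n_rep
    ctx_total = max(read_len - len(run), 8)
    left_len = int(rng.integers(4, ctx_total - 3))
    right_len = ctx_total - left_len
    # context must neither extend the planted run (boundary bases) nor carry
    # a chance SSR of its own
    while True:
        left = _random_seq(rng, left_len, 0.45)
        if left[-1] != motif[-1] and not find_ssrs(SequenceRecord(id="_c", seq=left)):
            break
    while True:
        right = _random_seq(rng, right_len, 0.45)
        if right[0] != motif[0] and not find_ssrs(SequenceRecord(id="_c", seq=right)):
            break
    return left + run + right, left_len + 1


def simulate_collection(
    config: SimulationConfig,
) -> tuple[list[SequenceRecord], pd.DataFrame, list[StructureFixture]]:
    """Generate the reads, the truth table and the hairpin structure fixtures."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    reads: list[SequenceRecord] = []
    truth_rows: list[dict] = []
    fixtures: list[StructureFixture] = []

    from .ssr_scan import find_ssrs

    for i in range(config.n_background):
        length = int(rng.integers(lo, hi + 1))
        # rejection-sample chance microsatellites out of the background so
        # that every SSR in the collection is a recorded planting
        while True:
            rec = SequenceRecord(
                id=f"bg-{i:05d}", seq=_random_seq(rng, length, config.gc_background)
            )
            if not find_ssrs(rec):
                break
        reads.append(rec)

    for spec in config.planted_mirnas:
        for c in range(spec.n_copies):
            # re-draw the random loop/flanks if they introduce a chance SSR,
            # so every SSR in the collection is a recorded planting
            while True:
                sub_seed = int(rng.integers(0, 2**31 - 1))
                read, fixture, span = make_hairpin(
                    spec.mature,
                    star_mismatches=spec.star_mismatches,
                    loop_len=spec.loop_len,
                    flank_len=spec.flank_len,
                    arm=spec.arm,
                    seed=sub_seed,
                )
                if not find_ssrs(read):
                    break
            if read.length > hi:
                raise ValueError(
                    f"planted precursor for {spec.mature.id} ({read.length} bp) "
                    f"exceeds the maximum read length {hi}"
                )
            read = SequenceRecord(id=f"mir-{spec.mature.id}-{c}", seq=read.seq)
            fixture = StructureFixture(read.id, fixture.structure, fixture.mfe)
            reads.append(read)
            fixtures.append(fixture)
            truth_rows.append(
                dict(
                    read_id=read.id,
                    feature_kind="mirna",
                    feature_id=spec.mature.id,
                    start=1,
                    end=read.length,
                    strand="+",
                    payload=f"arm={spec.arm};mature_start={span[0]};mature_end={span[1]};"
                    f"star_mismatches={spec.star_mismatches}",
                )
            )

    if config.planted_coding:
        for c in range(config.planted_coding):
            n_codons = int(rng.integers(100, 160))
            while True:
                seq, start, end = _make_coding_read(rng, n_codons)
                if not find_ssrs(SequenceRecord(id="_c", seq=seq)):
                    break
            if len(seq) > hi:
                raise ValueError("planted ORF read exceeds the maximum read length")
            rec = SequenceRecord(id=f"cds-{c:03d}", seq=seq)
            reads.append(rec)
            truth_rows.append(
                dict(
                    read_id=rec.id,
                    feature_kind="coding",
                    feature_id=f"orf-{c:03d}",
                    start=start,
                    end=end,
                    strand="+",
                    payload=f"n_codons={n_codons}",
                )
            )

    for spec in config.planted_ssrs:
        run_len = len(spec.motif) * spec.repeat_count
        if run_len + 8 > hi:
            raise ValueError(
                f"planted SSR ({spec.motif} x {spec.repeat_count}) exceeds "
                f"the maximum read length {hi}"
            )
        for c in range(spec.n_copies):
            read_len = int(rng.integers(max(lo, run_len + 8), hi + 1))
            seq, start = _embed_ssr(rng, spec.motif, spec.repeat_count, read_len)
            rec = SequenceRecord(id=f"ssr-{spec.motif}x{spec.repeat_count}-{c}", seq=seq)
            reads.append(rec)
            truth_rows.append(
                dict(
                    read_id=rec.id,
                    feature_kind="ssr",
                    feature_id=f"{spec.motif}x{spec.repeat_count}",
                    start=start,
                    end=start + run_len - 1,
                    strand="+",
                    payload=f"motif={spec.motif};n_repeats={spec.repeat_count}",
                )
            )

    for spec in config.planted_targets:
        for c in range(spec.n_copies):
            while True:
                sub_seed = int(rng.integers(0, 2**31 - 1))
                uni, span = make_target_unigene(
                    spec.mature, spec.penalty_budget, context_len=80, seed=sub_seed
                )
                if not find_ssrs(uni):
                    break
            if uni.length > hi:
                raise ValueError("planted target unigene exceeds the maximum read length")
            rec = SequenceRecord(id=f"tgt-{spec.mature.id}-{c}", seq=uni.seq)
            reads.append(rec)
            truth_rows.append(
                dict(
                    read_id=rec.id,
                    feature_kind="target",
                    feature_id=spec.mature.id,
                    start=span[0],
                    end=span[1],
                    strand="+",
                    payload=f"penalty={spec.penalty_budget}",
                )
            )

    truth = pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS))
    for row in truth.itertuples():
        read = next(r for r in reads if r.id == row.read_id)
        if not 1 <= row.start <= row.end <= read.length:  # pragma: no cover - guard
            raise AssertionError("truth span outside carrying read")
    return reads, truth, fixtures


def default_study_config(seed: int) -> SimulationConfig:
    """The package's reference study conditions for end-to-end validation.

    500 background reads of 50-700 bp at GC 0.45 (matching the read-length
    window of a 454 EST survey), eight planted pre-miRNA hairpins using
    published non-repetitive mature sequences across both arms and 0-2 star
    mismatches, an SSR ladder spanning motif lengths 2-6 at and above the
    detection thresholds, near-complementary target sites at penalty budgets
    0-3, and 20 protein-coding reads.
    """
    from .published import candidate_mirna_table

    table = candidate_mirna_table()
    matures = {
        row.name_: MatureMirna(id=row.name_, seq=row.mature_seq)
        for row in table.rename(columns={"name": "name_"}).itertuples()
    }
    # repeat-rich matures (miR5658, miR5021) excluded: their mature sequences
    # are themselves SSRs and would plant unrecorded repeat features
    hp_names = [
        "pgi-miR1128",
        "pgi-miR827",
        "pgi-miR1439",
        "pgi-miR396i-3p",
        "pgi-miR390b",
        "pgi-miR156b",
        "pgi-miR403b",
        "pgi-miR172",
    ]
    arms = ["5p", "3p", "3p", "3p", "5p", "5p", "3p", "3p"]
    mms = [0, 1, 2, 0, 1, 2, 0, 1]
    hairpins = tuple(
        HairpinSpec(mature=matures[n], star_mismatches=k, arm=a)
        for n, a, k in zip(hp_names, arms, mms)
    )
    ssrs = (
        SsrSpec("AG", 6, 3),
        SsrSpec("AG", 8, 2),
        SsrSpec("AT", 7, 2),
        SsrSpec("AAG", 5, 3),
        SsrSpec("ACG", 6, 2),
        SsrSpec("AAAG", 4, 2),
        SsrSpec("AATC", 5, 2),
        SsrSpec("AACGT", 4, 2),
        SsrSpec("AACGTC", 4, 2),
    )
    targets = tuple(
        TargetSpec(mature=matures[n], penalty_budget=b)
        for n, b in [
            ("pgi-miR1128", 0.0),
            ("pgi-miR827", 0.5),
            ("pgi-miR156b", 1.0),
            ("pgi-miR390b", 2.0),
            ("pgi-miR403b", 3.0),
        ]
    )
    return SimulationConfig(
        seed=seed,
        n_background=500,
        planted_mirnas=hairpins,
        planted_ssrs=ssrs,
        planted_targets=targets,
        planted_coding=20,
    )


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
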