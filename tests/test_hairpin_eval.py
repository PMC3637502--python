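from __future__ import annotations

import numpy as np
import pytest

from estmine._sequtils import dna_to_rna, round_half_up
from estmine.hairpin_eval import (
    FixtureEngine,
    MirnaRecord,
    amfe,
    assess_hairpin,
    call_mirna,
    gc_percent,
    mfei,
    mirna_family,
    pair_table,
)
from estmine.io_formats import MatureMirna
from estmine.mirna_homology import PrecursorCandidate
from estmine.synthetic_data import make_hairpin

MIR156B = MatureMirna(id="pgi-miR156b", seq="UGACAGAAGACUAGAGAGCAC")


class TestEnergyArithmetic:
    @pytest.mark.parametrize(
        "seq,expected", [("GGCC", 100.0), ("AUAU", 0.0), ("GCAU", 50.0)]
    )
    def test_gc_percent(self, seq, expected):
        assert gc_percent(seq) == expected

    def test_gc_percent_agrees_with_direct_tally(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGU"), size=290))
        assert gc_percent(seq) == pytest.approx(
            sum(1 for b in seq if b in "GC") / 290 * 100
        )

    def test_amfe_published_row_inputs(self):
        assert amfe(-99.2, 290) == pytest.approx(34.2069, abs=5e-4)

    def test_amfe_zero_energy(self):
        assert amfe(0.0, 100) == 0.0

    def test_amfe_rejects_zero_length(self):
        with pytest.raises(ValueError):
            amfe(-10.0, 0)

    @pytest.mark.parametrize(
        "mfe_abs,pl,gc,printed",
        [(99.2, 290, 22, 1.55), (43.2, 117, 32, 1.15), (21.9, 68, 38, 0.85)],
    )
    def test_mfei_spot_rows(self, mfe_abs, pl, gc, printed):
        assert round_half_up(mfei(-mfe_abs, pl, gc), 2) == printed

    def test_mfei_reproduces_every_published_row(self, published_table):
        for row in published_table.itertuples():
            got = round_half_up(mfei(-row.mfe_abs, row.precursor_len, row.gc_percent), 2)
            assert got == row.mfei, row.name

    def test_mfei_rejects_zero_gc(self):
        with pytest.raises(ValueError):
            mfei(-10.0, 100, 0.0)


class TestPairTable:
    def test_partner_symmetry(self):
        pt = pair_table("((..))")
        assert pt == [5, 4, -1, -1, 1, 0]

    @pytest.mark.parametrize("bad", ["(((..))", "())(", "(x)"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            pair_table(bad)


def _candidate_from_hairpin(mature, **kwargs):
    read, fixture, span = make_hairpin(mature, **kwargs)
    cand = PrecursorCandidate(
        read_id=read.id,
        mirna_id=mature.id,
        precursor_seq=dna_to_rna(read.seq),
        mature_start=span[0],
        mature_end=span[1],
    )
    return cand, fixture


class TestAssessHairpin:
    def test_perfect_five_prime_hairpin(self):
        cand, fixture = _candidate_from_hairpin(
            MIR156B, star_mismatches=0, loop_len=8, flank_len=10, arm="5p", seed=1
        )
        a = assess_hairpin(cand, fixture.structure)
        assert a.is_hairpin and a.arm == "5p"
        assert a.mature_star_mismatches == 0 and a.mature_unpaired == 0

    def test_three_prime_arm_detected(self):
        cand, fixture = _candidate_from_hairpin(
            MIR156B, star_mismatches=0, loop_len=8, flank_len=10, arm="3p", seed=2
        )
        assert assess_hairpin(cand, fixture.structure).arm == "3p"

    def test_mature_across_loop_spans(self):
        # structure pairs positions on both sides of the declared mature span
        structure = "((((((....))))))"
        cand = PrecursorCandidate(
            read_id="r",
            mirna_id="m",
            precursor_seq="GGGGGGAAAACCCCCC",
            mature_start=4,
            mature_end=13,
        )
        a = assess_hairpin(cand, structure)
        assert a.arm == "spanning" and not a.is_hairpin

    def test_unpaired_mature_budget_enforced(self):
        cand, fixture = _candidate_from_hairpin(
            MIR156B, star_mismatches=5, loop_len=8, flank_len=10, arm="5p", seed=3
        )
        tight = assess_hairpin(cand, fixture.structure, max_mature_unpaired=4)
        loose = assess_hairpin(cand, fixture.structure, max_mature_unpaired=6)
        assert not tight.is_hairpin and loose.is_hairpin

    def test_length_mismatch_rejected(self):
        cand, fixture = _candidate_from_hairpin(MIR156B, seed=4)
        with pytest.raises(ValueError, match="length"):
            assess_hairpin(cand, fixture.structure[:-1])


def _fixture_engine(pairs):
    return FixtureEngine({seq: (structure, mfe) for seq, structure, mfe in pairs})


class TestCallMirna:
    def _planted(self, seed=5, **kwargs):
        cand, fixture = _candidate_from_hairpin(MIR156B, seed=seed, **kwargs)
        engine = _fixture_engine([(cand.precursor_seq, fixture.structure, fixture.mfe)])
        return cand, engine

    def test_planted_hairpin_yields_one_record(self):
        cand, engine = self._planted()
        records = call_mirna([cand], engine)
        assert len(records) == 1
        rec = records[0]
        assert rec.arm == "5p" and rec.source_read == cand.read_id
        assert rec.mature_seq == MIR156B.seq

    def test_mfei_boundary_inclusive(self):
        # engineer MFE so MFEI is exactly 0.85: |MFE| = 0.85 * gc * len / 100
        cand, _ = _candidate_from_hairpin(MIR156B, seed=6)
        gc = gc_percent(cand.precursor_seq)
        _, fixture = _candidate_from_hairpin(MIR156B, seed=6)
        exact_mfe = -0.85 * gc * cand.length / 100
        engine = _fixture_engine([(cand.precursor_seq, fixture.structure, exact_mfe)])
        assert len(call_mirna([cand], engine, mfei_min=0.85)) == 1
        engine_below = _fixture_engine(
            [(cand.precursor_seq, fixture.structure, exact_mfe + 0.2)]
        )
        assert call_mirna([cand], engine_below, mfei_min=0.85) == []

    def test_topology_failure_yields_no_record(self):
        cand, _ = self._planted()
        flat = "." * cand.length
        engine = _fixture_engine([(cand.precursor_seq, flat, -50.0)])
        assert call_mirna([cand], engine) == []

    def test_order_invariance(self):
        pairs = []
        cands = []
        for seed in (7, 8, 9):
            cand, fixture = _candidate_from_hairpin(MIR156B, seed=seed)
            cand = PrecursorCandidate(
                read_id=f"read{seed}",
                mirna_id=MIR156B.id,
                precursor_seq=cand.precursor_seq,
                mature_start=cand.mature_start,
                mature_end=cand.mature_end,
            )
            pairs.append((cand.precursor_seq, fixture.structure, fixture.mfe))
            cands.append(cand)
        engine = _fixture_engine(pairs)
        fwd = call_mirna(cands, engine)
        rev = call_mirna(list(reversed(cands)), engine)
        assert fwd == rev and len(fwd) == 3

    def test_missing_structure_names_candidate(self):
        cand, _ = self._planted()
        with pytest.raises(KeyError, match=cand.read_id):
            call_mirna([cand], _fixture_engine([]))


class TestMirnaRecordInvariant:
    def test_inconsistent_mfei_rejected(self):
        with pytest.raises(ValueError, match="MFEI"):
            MirnaRecord(
                name="x", query_mirna="q", mature_len=21, mature_seq="A" * 21,
                n_mismatches_to_query=0, arm="5p", gc_percent=40.0,
                precursor_len=100, mfe_abs=40.0, mfei=2.0, source_read="r",
            )

    def test_published_rows_satisfy_consistency(self, published_records):
        assert len(published_records) == 14  # constructor validates each row


def test_family_strips_species_prefix():
    assert mirna_family("vun-miR156b") == "miR156b"
    assert mirna_family("custom") == "custom"
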