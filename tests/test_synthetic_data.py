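from __future__ import annotations

import numpy as np
import pytest

from estmine._sequtils import dna_to_rna, revcomp_dna, rna_to_dna
from estmine.hairpin_eval import assess_hairpin
from estmine.io_formats import MatureMirna
from estmine.mirna_homology import PrecursorCandidate
from estmine.synthetic_data import (
    HairpinSpec,
    SimulationConfig,
    SsrSpec,
    TargetSpec,
    make_hairpin,
    make_target_unigene,
    simulate_collection,
)
from estmine.target_prediction import find_targets, score_site

MIR156B = MatureMirna(id="pgi-miR156b", seq="UGACAGAAGACUAGAGAGCAC")


class TestMakeHairpin:
    def test_perfect_duplex_geometry(self):
        read, fixture, span = make_hairpin(
            MIR156B, star_mismatches=0, loop_len=8, flank_len=10, arm="5p", seed=1
        )
        assert read.length == 21 + 21 + 8 + 20
        # all 21 mature bases paired in the fixture
        assert fixture.structure[span[0] - 1 : span[1]].count("(") == 21

    @pytest.mark.parametrize("arm", ["5p", "3p"])
    def test_mature_sits_on_requested_side_of_loop(self, arm):
        read, fixture, span = make_hairpin(
            MIR156B, star_mismatches=1, loop_len=9, flank_len=12, arm=arm, seed=7
        )
        loop_start = 12 + 21 + 1
        loop_end = 12 + 21 + 9
        if arm == "5p":
            assert span[0] <= loop_start
        else:
            assert span[0] > loop_end

    @pytest.mark.parametrize("k", range(7))
    def test_star_mismatch_count_matches_planting(self, k):
        """Planted mismatch count equals a position-wise star/revcomp comparison
        and the hairpin assessment's bulge count."""
        read, fixture, span = make_hairpin(
            MIR156B, star_mismatches=k, loop_len=8, flank_len=10, arm="5p", seed=k + 3
        )
        mature_dna = read.seq[span[0] - 1 : span[1]]
        star = read.seq[span[1] + 8 : span[1] + 8 + 21]
        direct = sum(1 for a, b in zip(star, revcomp_dna(mature_dna)) if a != b)
        assert direct == k
        cand = PrecursorCandidate(
            read_id=read.id,
            mirna_id=MIR156B.id,
            precursor_seq=dna_to_rna(read.seq),
            mature_start=span[0],
            mature_end=span[1],
        )
        assert assess_hairpin(cand, fixture.structure).mature_star_mismatches == k

    def test_stub_energy_is_two_per_pair(self):
        _, fixture, _ = make_hairpin(MIR156B, 0, loop_len=8, flank_len=10, seed=2)
        assert fixture.mfe == -2.0 * fixture.structure.count("(")

    def test_mature_with_n_rejected(self):
        bad = MatureMirna(id="m", seq="N" + "A" * 20)
        with pytest.raises(ValueError, match="N"):
            make_hairpin(bad, seed=0)


class TestSimulateCollection:
    def test_single_planted_ssr_truth_row(self):
        cfg = SimulationConfig(
            seed=5, n_background=0, planted_ssrs=(SsrSpec("AG", 7, 1),)
        )
        reads, truth, fixtures = simulate_collection(cfg)
        assert len(reads) == 1 and len(truth) == 1
        row = truth.iloc[0]
        assert row.feature_kind == "ssr"
        assert row.end - row.start + 1 == 14

    def test_same_seed_identical_output(self, tmp_path):
        from estmine.io_formats import write_fasta

        cfg = SimulationConfig(
            seed=1,
            n_background=25,
            planted_mirnas=(HairpinSpec(MIR156B),),
            planted_ssrs=(SsrSpec("AAG", 6, 2),),
            planted_coding=2,
        )
        out = []
        for run in range(2):
            reads, truth, fixtures = simulate_collection(cfg)
            p = tmp_path / f"run{run}.fasta"
            write_fasta(reads, p)
            out.append((p.read_bytes(), truth.to_csv(), [f.structure for f in fixtures]))
        assert out[0] == out[1]

    def test_background_gc_close_to_requested(self):
        cfg = SimulationConfig(seed=3, n_background=1000, gc_background=0.40)
        reads, _, _ = simulate_collection(cfg)
        seq = "".join(r.seq for r in reads)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.39 <= gc <= 0.41

    def test_lengths_within_configured_range(self):
        cfg = SimulationConfig(seed=9, n_background=200, length_range=(50, 300))
        reads, _, _ = simulate_collection(cfg)
        assert all(50 <= r.length <= 300 for r in reads)

    def test_truth_spans_lie_within_reads(self, study_collection):
        _, reads, truth, _ = study_collection
        lengths = {r.id: r.length for r in reads}
        for row in truth.itertuples():
            assert 1 <= row.start <= row.end <= lengths[row.read_id]

    def test_oversized_planting_rejected(self):
        cfg = SimulationConfig(
            seed=1,
            n_background=0,
            length_range=(50, 60),
            planted_ssrs=(SsrSpec("ACGTAC", 20, 1),),
        )
        with pytest.raises(ValueError, match="exceeds"):
            simulate_collection(cfg)


class TestMakeTargetUnigene:
    def test_zero_budget_site_is_exact_reverse_complement(self):
        uni, span = make_target_unigene(MIR156B, penalty_budget=0.0, seed=4)
        site = uni.seq[span[0] - 1 : span[1]]
        assert site == revcomp_dna(rna_to_dna(MIR156B.seq))
        assert score_site(MIR156B, site) == 0.0

    @pytest.mark.parametrize("budget", [0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0])
    def test_recorded_penalty_equals_budget(self, budget):
        uni, span = make_target_unigene(MIR156B, budget, seed=int(budget * 10) + 1)
        site = uni.seq[span[0] - 1 : span[1]]
        assert score_site(MIR156B, site) == pytest.approx(budget)

    def test_half_unit_budget_needs_wobble_capable_mature(self):
        no_gu = MatureMirna(id="m", seq="AC" * 10)  # no G or U anywhere
        with pytest.raises(ValueError, match="unreachable"):
            make_target_unigene(no_gu, penalty_budget=0.5, seed=1)

    def test_planted_sites_recovered_by_scanner(self):
        rng = np.random.default_rng(17)
        matures = [MIR156B, MatureMirna(id="pgi-miR827", seq="UUAGAUGAUCAUCAGCAAACA")]
        unis, expected = [], []
        for trial in range(50):
            budget = float(rng.integers(0, 9)) / 2.0  # 0 .. 4.0
            m = matures[trial % 2]
            uni, span = make_target_unigene(m, budget, seed=1000 + trial)
            uni = type(uni)(id=f"u{trial}", seq=uni.seq)
            unis.append(uni)
            expected.append((m.id, uni.id, span[0], span[1], budget))
        hits = find_targets(matures, unis, max_penalty=4.0)
        hit_set = {(h.mirna_id, h.unigene_id, h.site_start, h.site_end, h.penalty) for h in hits}
        for item in expected:
            assert item in hit_set
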