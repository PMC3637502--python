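from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from estmine.io_formats import SequenceRecord
from estmine.published import (
    ASSEMBLY_TOTAL_BASES,
    N_SSRS,
    ssr_repeat_matrix,
)
from estmine.ssr_scan import (
    DEFAULT_THRESHOLDS,
    SsrRecord,
    find_ssrs,
    is_primitive,
    motif_class,
    scan_collection,
    ssr_density,
    summarize_ssrs,
)

from _oracles import revcomp, ssr_oracle


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestFindSsrs:
    def test_embedded_di_run_coordinates(self):
        seq = "TCTGACTGAC" + "AG" * 6 + "CCATTGCA"
        recs = find_ssrs(SequenceRecord(id="r", seq=seq))
        assert len(recs) == 1
        r = recs[0]
        assert (r.motif, r.n_repeats, r.start, r.end) == ("AG", 6, 11, 22)

    def test_five_di_repeats_below_threshold(self):
        recs = find_ssrs(SequenceRecord(id="r", seq="TCTGACTGAC" + "AG" * 5 + "CCTTGCA"))
        assert recs == []

    @pytest.mark.parametrize(
        "motif,reps,expect",
        [("AG", 6, True), ("AG", 5, False), ("AAG", 5, True), ("AAG", 4, False),
         ("AAAG", 4, True), ("AACGT", 4, True), ("AACGTC", 4, True)],
    )
    def test_thresholds_per_motif_length(self, motif, reps, expect):
        seq = "TCTGACTGCA" + motif * reps + "TTCACTGA"
        recs = find_ssrs(SequenceRecord(id="r", seq=seq))
        assert bool(recs) == expect
        if expect:
            assert recs[0].motif == motif and recs[0].n_repeats == reps

    def test_run_attributed_to_primitive_motif(self):
        recs = find_ssrs(SequenceRecord(id="r", seq="CCGTTG" + "AT" * 6 + "GCCTGA"))
        assert [(r.motif, r.n_repeats) for r in recs] == [("AT", 6)]

    def test_runs_containing_n_excluded(self):
        seq = "TCTGACTGAC" + "AG" * 3 + "NG" + "AG" * 2 + "CCATTGCA"
        assert find_ssrs(SequenceRecord(id="r", seq=seq)) == []

    def test_partial_trailing_copy_not_counted(self):
        seq = "TCTGACTGCC" + "AAG" * 5 + "AA" + "TCACTGA"
        recs = find_ssrs(SequenceRecord(id="r", seq=seq))
        assert [(r.n_repeats, r.end) for r in recs] == [(5, 25)]

    def test_equivalence_with_brute_force_enumerator(self):
        rng = np.random.default_rng(31)
        motifs = ["AG", "AT", "AAG", "ACG", "AAAG", "AACGT", "AACGTC"]
        for trial in range(500):
            seq = _rand_seq(rng, int(rng.integers(20, 90)))
            if trial % 2 == 0:
                m = motifs[trial % len(motifs)]
                reps = int(rng.integers(3, 9))
                pos = int(rng.integers(0, len(seq)))
                seq = seq[:pos] + m * reps + seq[pos:]
            got = [
                (r.start, r.end, r.motif, r.n_repeats)
                for r in find_ssrs(SequenceRecord(id="r", seq=seq))
            ]
            assert sorted(got) == ssr_oracle(seq, dict(DEFAULT_THRESHOLDS))


class TestMotifClass:
    def test_published_dominant_motif_examples(self):
        assert motif_class("GA") == "AG/CT"
        assert motif_class("CT") == "AG/CT"
        assert motif_class("AG") == "AG/CT"

    def test_exhaustive_di_tri_idempotent_and_strand_invariant(self):
        for k in (2, 3):
            for motif in map("".join, product("ACGT", repeat=k)):
                if not is_primitive(motif):
                    continue
                label = motif_class(motif)
                assert motif_class(revcomp(motif)) == label
                for i in range(k):  # rotation invariance
                    assert motif_class(motif[i:] + motif[:i]) == label
                left = label.split("/")[0]
                assert motif_class(left) == label  # idempotent canonical form

    def test_non_primitive_rejected(self):
        with pytest.raises(ValueError):
            motif_class("ATAT")


def _records_from_matrix(matrix):
    """Expand the published count matrix into an input-equivalent record multiset."""
    recs = []
    i = 0
    for motif_len, row in matrix.iterrows():
        base = {2: "AG", 3: "AAG", 4: "AAAG", 5: "AACGT", 6: "AACGTC"}[motif_len]
        for bin_label, count in row.items():
            reps = 11 if bin_label == ">10" else int(bin_label)
            for _ in range(int(count)):
                recs.append(
                    SsrRecord(
                        unigene_id="uni",
                        motif=base,
                        n_repeats=reps,
                        start=1,
                        end=motif_len * reps,
                    )
                )
                i += 1
    return recs


class TestSummaries:
    def test_published_matrix_totals(self):
        matrix = ssr_repeat_matrix()
        recs = _records_from_matrix(matrix)
        uni = SequenceRecord(id="uni", seq="A" * 100)
        summary = summarize_ssrs(recs, [uni])
        assert list(summary.row_totals()) == [6659, 3635, 1455, 532, 763]
        assert summary.n_ssrs == 13044
        assert summary.matrix.equals(matrix)

    def test_published_density_identity(self):
        assert ssr_density(N_SSRS, ASSEMBLY_TOTAL_BASES) == 172.5

    def test_di_bins_below_threshold_structurally_empty(self, study_collection):
        _, reads, _, _ = study_collection
        summary = summarize_ssrs(scan_collection(reads), reads)
        assert summary.matrix.loc[2, "4"] == 0 and summary.matrix.loc[2, "5"] == 0

    def test_synthetic_matrix_equals_planting_design(self, study_collection):
        config, reads, truth, _ = study_collection
        summary = summarize_ssrs(scan_collection(reads), reads)
        expected = {}
        for spec in config.planted_ssrs:
            key = (len(spec.motif), str(spec.repeat_count) if spec.repeat_count <= 10 else ">10")
            expected[key] = expected.get(key, 0) + spec.n_copies
        for (mlen, bin_label), count in expected.items():
            assert summary.matrix.loc[mlen, bin_label] == count
        assert summary.n_ssrs == sum(expected.values())

    def test_unknown_unigene_rejected(self):
        rec = SsrRecord(unigene_id="ghost", motif="AG", n_repeats=6, start=1, end=12)
        with pytest.raises(KeyError):
            summarize_ssrs([rec], [SequenceRecord(id="u", seq="A" * 50)])

    def test_per_unigene_counts(self):
        u1 = SequenceRecord(id="u1", seq="GTCACTGTCC" + "AG" * 6 + "TCGATCGGTC" + "AAG" * 5 + "TTGCAGT")
        u2 = SequenceRecord(id="u2", seq="GTCACTGTCCTTGAGTGACA")
        recs = scan_collection([u1, u2])
        s = summarize_ssrs(recs, [u1, u2])
        assert s.n_unigenes_with_ssr == 1 and s.n_unigenes_with_2plus == 1
        assert s.motif_class_frequencies == {"AG/CT": 50.0, "AAG/CTT": 50.0}
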