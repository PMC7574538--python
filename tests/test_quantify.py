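"""Window-based modification calling and allele tabulation."""

import numpy as np
import pytest

from oracles import left_shift_deletion, left_shift_insertion
from scindel.align import align_semiglobal
from scindel.panel import Amplicon, compute_cut_site
from scindel.quantify import (build_edit_matrix, classify_read, quantify_bulk,
                              summarize_cell_amplicon, window_allele)
from scindel.simulate import synthetic_panel


@pytest.fixture(scope="module")
def toy_amplicon():
    """A 90-bp on-target amplicon with the cut near the middle."""
    rng = np.random.default_rng(99)
    seq = "".join("ACGT"[c] for c in rng.integers(0, 4, 90))
    pam_start = 45
    seq = seq[:pam_start] + "AGG" + seq[pam_start + 3:]
    amp = Amplicon("toy", seq, "on_target",
                   guide_spacer=seq[pam_start - 20:pam_start],
                   guide_strand="forward")
    compute_cut_site(amp)
    return amp


class TestClassifyRead:
    def test_perfect_read_unmodified(self, toy_amplicon):
        aln = align_semiglobal(toy_amplicon.ref_seq, toy_amplicon.ref_seq)
        assert classify_read(aln, toy_amplicon) is False

    def test_deletion_spanning_cut_is_modified(self, toy_amplicon):
        cut = toy_amplicon.cut_site
        ref = toy_amplicon.ref_seq
        read = ref[:cut - 1] + ref[cut + 2:]
        aln = align_semiglobal(read, ref)
        assert classify_read(aln, toy_amplicon) is True

    def test_deletion_far_downstream_unmodified(self, toy_amplicon):
        lo, hi = toy_amplicon.window
        ref = toy_amplicon.ref_seq
        read = ref[:hi + 10] + ref[hi + 12:]
        aln = align_semiglobal(read, ref)
        assert classify_read(aln, toy_amplicon) is False

    def test_all_two_base_deletion_placements(self, toy_amplicon):
        """Interval-intersection oracle over every 2-bp deletion placement."""
        ref = toy_amplicon.ref_seq
        lo, hi = toy_amplicon.window
        for start in range(5, len(ref) - 7):
            read = ref[:start] + ref[start + 2:]
            aln = align_semiglobal(read, ref)
            norm_start = left_shift_deletion(ref, start, 2)
            expected = norm_start < hi and norm_start + 2 > lo
            assert classify_read(aln, toy_amplicon) is expected, start

    def test_insertion_placements_closed_window(self, toy_amplicon):
        """2-bp insertions: insertion point tested against the closed window."""
        ref = toy_amplicon.ref_seq
        lo, hi = toy_amplicon.window
        for point in range(5, len(ref) - 5):
            ins = "TG" if ref[point - 1] != "G" else "TC"
            read = ref[:point] + ins + ref[point:]
            aln = align_semiglobal(read, ref)
            norm_point, _ = left_shift_insertion(ref, point, ins)
            expected = lo <= norm_point <= hi
            assert classify_read(aln, toy_amplicon) is expected, point

    def test_substitution_in_window_counts_only_when_enabled(self, toy_amplicon):
        ref = toy_amplicon.ref_seq
        cut = toy_amplicon.cut_site
        read = ref[:cut] + ("A" if ref[cut] != "A" else "C") + ref[cut + 1:]
        aln = align_semiglobal(read, ref)
        assert classify_read(aln, toy_amplicon) is False
        assert classify_read(aln, toy_amplicon, count_substitutions=True) is True

    def test_control_amplicon_rejected(self):
        panel = synthetic_panel(n_targets=1, n_controls=1, seed=21)
        ctrl = panel["ctrl_0"]
        aln = align_semiglobal(ctrl.ref_seq, ctrl.ref_seq)
        with pytest.raises(ValueError, match="window"):
            classify_read(aln, ctrl)


class TestWindowAllele:
    def test_reference_read_projects_reference(self, toy_amplicon):
        ref = toy_amplicon.ref_seq
        aln = align_semiglobal(ref, ref)
        lo, hi = toy_amplicon.window
        expected = ref[max(0, lo - 10):min(len(ref), hi + 10)]
        assert window_allele(aln, toy_amplicon, ref) == expected

    def test_distal_errors_do_not_change_allele(self, toy_amplicon):
        ref = toy_amplicon.ref_seq
        read = ("A" if ref[0] != "A" else "C") + ref[1:]
        a1 = window_allele(align_semiglobal(ref, ref), toy_amplicon, ref)
        a2 = window_allele(align_semiglobal(read, ref), toy_amplicon, read)
        assert a1 == a2

    def test_deletion_marked_with_gaps(self, toy_amplicon):
        ref = toy_amplicon.ref_seq
        cut = toy_amplicon.cut_site
        read = ref[:cut - 1] + ref[cut + 2:]
        allele = window_allele(align_semiglobal(read, ref), toy_amplicon, read)
        assert "-" in allele


class TestSummaries:
    def test_four_reads_is_no_call(self):
        calls = [(False, "AAAA")] * 4
        assert summarize_cell_amplicon("bc", "amp", calls, min_reads=5) is None

    def test_all_reference_reads(self):
        calls = [(False, "AAAA")] * 10
        s = summarize_cell_amplicon("bc", "amp", calls)
        assert s.pct_modified == 0.0
        assert s.heterozygosity == 0.0
        assert s.allele1.count == 10
        assert s.allele2 is None

    def test_six_four_split(self):
        calls = [(True, "A--A")] * 6 + [(False, "AAAA")] * 4
        s = summarize_cell_amplicon("bc", "amp", calls)
        assert s.pct_modified == pytest.approx(60.0)
        assert s.allele1.modified is True
        assert s.allele1.frequency == pytest.approx(0.6)
        assert s.allele2.modified is False
        assert s.allele2.frequency == pytest.approx(0.4)
        assert s.heterozygosity == pytest.approx(40.0)

    def test_allele_frequencies_sum_to_one(self, rng):
        alleles = ["A", "B", "C", "D"]
        calls = [(False, alleles[rng.integers(4)]) for _ in range(50)]
        s = summarize_cell_amplicon("bc", "amp", calls)
        from collections import Counter
        freqs = Counter(seq for _, seq in calls)
        assert sum(c / 50 for c in freqs.values()) == pytest.approx(1.0)
        assert s.allele1.count >= s.allele2.count

    def test_tie_broken_lexicographically(self):
        calls = [(False, "BBBB")] * 5 + [(False, "AAAA")] * 5
        s = summarize_cell_amplicon("bc", "amp", calls)
        assert s.allele1.allele_seq == "AAAA"


class TestEditMatrix:
    def _summary(self, bc, amp, pct):
        return summarize_cell_amplicon(
            bc, amp, [(True, "x")] * int(pct / 10) + [(False, "y")] * (10 - int(pct / 10)))

    def test_dense_matrix(self):
        summaries = [self._summary(bc, amp, 50)
                     for bc in ("c1", "c2") for amp in ("a1", "a2", "a3")]
        pct, cov = build_edit_matrix(summaries)
        assert pct.shape == (2, 3)
        assert not pct.isna().any().any()
        assert (cov == 10).all().all()

    def test_missing_entry(self):
        summaries = [self._summary("c1", "a1", 50), self._summary("c1", "a2", 0),
                     self._summary("c2", "a1", 100)]
        pct, _ = build_edit_matrix(summaries, cells=["c1", "c2"],
                                   amplicons=["a1", "a2"])
        assert pct.isna().sum().sum() == 1
        assert np.isnan(pct.loc["c2", "a2"])

    def test_duplicate_summary_rejected(self):
        s = self._summary("c1", "a1", 50)
        with pytest.raises(ValueError, match="duplicate"):
            build_edit_matrix([s, s])


class TestBulk:
    def test_85_of_100_reads_modified(self):
        panel = synthetic_panel(n_targets=1, seed=33)
        amp = panel.amplicons[0]
        cut = amp.cut_site
        edited = amp.ref_seq[:cut - 1] + amp.ref_seq[cut + 2:]
        reads = [edited] * 85 + [amp.ref_seq] * 15
        table = quantify_bulk(reads, panel)
        row = table.set_index("amplicon_id").loc[amp.amplicon_id]
        assert row["n_reads"] == 100
        assert row["pct_modified"] == pytest.approx(85.0)

    def test_empty_input(self):
        panel = synthetic_panel(n_targets=1, seed=33)
        table = quantify_bulk([], panel)
        assert len(table) == 0

    def test_binomial_sampling_recovers_mix_fraction(self):
        """50/50 edited mix at n=10000: estimate within 3 binomial s.e."""
        rng = np.random.default_rng(77)
        panel = synthetic_panel(n_targets=1, seed=33)
        amp = panel.amplicons[0]
        cut = amp.cut_site
        edited = amp.ref_seq[:cut - 1] + amp.ref_seq[cut + 2:]
        n = 10_000
        k = rng.binomial(n, 0.5)
        reads = [edited] * k + [amp.ref_seq] * (n - k)
        table = quantify_bulk(reads, panel)
        pct = table["pct_modified"].iloc[0]
        se = 100 * np.sqrt(0.25 / n)
        assert abs(pct - 50.0) <= 3 * se
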