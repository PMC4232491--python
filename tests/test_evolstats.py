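import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import oracles
from conftest import random_dna
from ncxtools import evolstats
from ncxtools.codonaln import CodonAlignment, CodonError
from ncxtools.evolstats import (
    DnDsResult,
    global_dnds,
    jc69,
    ng86_pair,
    pairwise_pi,
    sliding_window_pi,
    summarize_diversity,
)
from ncxtools.seqio import Alignment, SeqRecord


class TestPairwisePi:
    def test_single_difference(self):
        assert pairwise_pi("AAAA", "AAAT") == (0.25, 4)

    def test_gap_exclusion(self):
        pi, valid = pairwise_pi("AA-A", "AATA")
        assert pi == 0 and valid == 3

    def test_ambiguity_excluded(self):
        pi, valid = pairwise_pi("AANA", "AATA")
        assert valid == 3

    def test_no_valid_sites(self):
        assert pairwise_pi("---", "AAA") == (None, 0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pairwise_pi("AA", "AAA")

    @given(st.text(alphabet="ACGT-N", min_size=1, max_size=60),
           st.text(alphabet="ACGT-N", min_size=1, max_size=60))
    def test_symmetry(self, a, b):
        n = min(len(a), len(b))
        assert pairwise_pi(a[:n], b[:n]) == pairwise_pi(b[:n], a[:n])


class TestSlidingWindow:
    def test_window_layout_150_100_25(self):
        rows = ["A" * 150, "A" * 150]
        windows = sliding_window_pi(rows, window=100, step=25)
        assert [(w.start, w.end) for w in windows] == [(0, 100), (25, 125), (50, 150)]

    def test_short_alignment_warns_empty(self):
        with pytest.warns(UserWarning):
            assert sliding_window_pi(["AAA", "AAA"], window=10, step=5) == []

    def test_all_gap_window_undefined(self):
        rows = ["-" * 10 + "A" * 10, "A" * 10 + "A" * 10]
        windows = sliding_window_pi(rows, window=10, step=10)
        assert windows[0].pi is None and windows[0].valid_sites == 0
        assert windows[1].pi == 0.0

    def test_window_equals_slice_oracle(self, rng):
        rows = [random_dna(rng, 200), random_dna(rng, 200)]
        for w in sliding_window_pi(rows, window=50, step=20):
            pi, valid = pairwise_pi(rows[0][w.start : w.end], rows[1][w.start : w.end])
            assert w.pi == pi and w.valid_sites == valid

    def test_multirow_mean_over_pairs(self, rng):
        rows = [random_dna(rng, 60) for _ in range(3)]
        (w,) = sliding_window_pi(rows, window=60, step=60)
        pis = [pairwise_pi(rows[i], rows[j])[0]
               for i, j in ((0, 1), (0, 2), (1, 2))]
        assert w.pi == pytest.approx(float(np.mean(pis)))

    def test_row_order_invariance(self, rng):
        rows = [random_dna(rng, 120) for _ in range(3)]
        a = sliding_window_pi(rows)
        b = sliding_window_pi(rows[::-1])
        assert [(w.pi, w.valid_sites) for w in a] == [(w.pi, w.valid_sites) for w in b]

    def test_nonoverlapping_mean_equals_whole_region(self, rng):
        # step == window: weighted window mean equals pi over the covered span
        rows = [random_dna(rng, 300), random_dna(rng, 300)]
        windows = sliding_window_pi(rows, window=50, step=50)
        total_diffs = sum(w.pi * w.valid_sites for w in windows)
        total_valid = sum(w.valid_sites for w in windows)
        whole = pairwise_pi(rows[0][:300], rows[1][:300])
        assert total_diffs / total_valid == pytest.approx(whole[0])


class TestSummarize:
    @staticmethod
    def _windows(values):
        return [
            evolstats.WindowDiversity(start=0, end=1, midpoint=0.5, pi=v, valid_sites=1)
            for v in values
        ]

    def test_mean_and_variance(self):
        s = summarize_diversity(self._windows([0.2, 0.3, 0.4]), "g")
        assert s.mean_pi == pytest.approx(0.3)
        assert s.window_variance == pytest.approx(0.01)

    def test_single_window(self):
        s = summarize_diversity(self._windows([0.5]), "g")
        assert s.mean_pi == 0.5 and s.window_variance == 0.0 and s.n_windows == 1

    def test_quartiles_linear_interpolation(self):
        s = summarize_diversity(self._windows([0.1, 0.2, 0.3, 0.4]), "g")
        assert s.q1 == pytest.approx(0.175)
        assert s.median == pytest.approx(0.25)
        assert s.q3 == pytest.approx(0.325)

    def test_ordering_invariant(self):
        s = summarize_diversity(self._windows([0.4, 0.1, 0.3, 0.2]), "g")
        assert s.minimum <= s.q1 <= s.median <= s.q3 <= s.maximum

    def test_no_defined_windows_raises(self):
        with pytest.raises(ValueError):
            summarize_diversity(self._windows([None]), "g")

    def test_whiskers_within_bounds(self):
        s = summarize_diversity(self._windows([0.1, 0.11, 0.12, 0.13, 0.9]), "g")
        assert s.whisker_high < 0.9
        assert s.maximum == 0.9


class TestNg86Pair:
    def test_synonymous_lysine(self):
        res = ng86_pair("AAA", "AAG")
        assert res.Sd == 1.0 and res.Nd == 0.0
        assert res.dN == 0.0

    def test_ttt_tta_counts(self):
        res = ng86_pair("TTT", "TTA")
        assert res.S == pytest.approx(0.5)
        assert res.N == pytest.approx(2.5)
        assert (res.Nd, res.Sd) == (1.0, 0.0)
        assert res.pN == pytest.approx(0.4)
        assert res.dS == 0.0
        assert res.omega is None

    def test_identical_rows(self):
        res = ng86_pair("ATGAAATTT", "ATGAAATTT")
        assert res.Nd == res.Sd == 0.0
        assert res.dN == res.dS == 0.0
        assert res.omega is None

    def test_gap_codon_skipped_pairwise(self):
        res = ng86_pair("ATG---AAA", "ATGTTTAAA")
        assert res.compared_codons == 2

    def test_stop_codon_raises(self):
        with pytest.raises(CodonError):
            ng86_pair("TAAAAA", "TAAAAA")

    def test_site_conservation(self):
        res = ng86_pair("ATGAAATTTCCC", "ATGAAGTTCCCA")
        assert res.N + res.S == pytest.approx(3 * res.compared_codons)

    def test_jc_correction_values(self):
        assert jc69(0.0) == 0.0
        assert jc69(0.1) == pytest.approx(-0.75 * math.log(1 - 0.4 / 3))
        assert jc69(0.75) is None


class TestNg86Oracle:
    def test_sites_match_oracle_all_sense_codons(self):
        from ncxtools.evolstats import codon_syn_sites
        from ncxtools.simulate import SENSE_CODONS

        for codon in SENSE_CODONS:
            assert codon_syn_sites(codon) == pytest.approx(
                oracles.ng86_sites_oracle(codon)
            )

    def test_differences_match_oracle_sample(self, rng):
        from ncxtools.evolstats import codon_path_differences
        from ncxtools.simulate import SENSE_CODONS

        codons = list(SENSE_CODONS)
        for _ in range(300):
            c1, c2 = rng.choice(codons), rng.choice(codons)
            got = codon_path_differences(str(c1), str(c2))
            want = oracles.ng86_diffs_oracle(str(c1), str(c2))
            if want is None:
                assert got is None
            else:
                assert got[0] == pytest.approx(want[0])
                assert got[1] == pytest.approx(want[1])


def _caln(*rows):
    recs = [SeqRecord(id=f"r{i}", residues=s) for i, s in enumerate(rows)]
    prot = Alignment([SeqRecord(id=r.id, residues="M" * (len(rows[0]) // 3))
                      for r in recs])
    return CodonAlignment(records=recs, source_protein_alignment=prot)


class TestGlobalDnds:
    def test_two_rows_reduces_to_pair(self):
        a, b = "ATGAAATTT", "ATGAAGTTA"
        pooled, per_pair = global_dnds(_caln(a, b))
        single = ng86_pair(a, b)
        assert pooled.N == pytest.approx(single.N)
        assert pooled.Nd == pytest.approx(single.Nd)
        assert pooled.omega == (pytest.approx(single.omega)
                                if single.omega is not None else None)
        assert len(per_pair) == 1

    def test_three_identical_rows(self):
        pooled, _ = global_dnds(_caln("ATGAAA", "ATGAAA", "ATGAAA"))
        assert pooled.Nd == pooled.Sd == 0.0
        assert pooled.omega is None

    def test_pooled_equals_pairwise_sums(self, rng):
        from ncxtools.simulate import SENSE_CODONS

        rows = ["".join(rng.choice(SENSE_CODONS, size=30)) for _ in range(4)]
        pooled, per_pair = global_dnds(_caln(*rows))
        assert pooled.N == pytest.approx(sum(r.N for _, _, r in per_pair))
        assert pooled.S == pytest.approx(sum(r.S for _, _, r in per_pair))
        assert pooled.Nd == pytest.approx(sum(r.Nd for _, _, r in per_pair))
        assert pooled.Sd == pytest.approx(sum(r.Sd for _, _, r in per_pair))

    def test_row_order_invariance(self, rng):
        from ncxtools.simulate import SENSE_CODONS

        rows = ["".join(rng.choice(SENSE_CODONS, size=20)) for _ in range(3)]
        a, _ = global_dnds(_caln(*rows))
        b, _ = global_dnds(_caln(*rows[::-1]))
        for attr in ("N", "S", "Nd", "Sd"):
            assert getattr(a, attr) == pytest.approx(getattr(b, attr))
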