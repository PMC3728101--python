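import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from concerted import (
    CodingMap,
    SaturationError,
    column_entropy,
    divergence_between_groups,
    global_dxy,
    jukes_cantor,
    nei_gojobori_pair,
    pi_by_class,
    sliding_dxy,
    tajima_d,
)
from conftest import make_aln

CODONS = [c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
          if oracles.GENETIC_CODE[c] != "*"]


class TestJukesCantor:
    def test_closed_form_value(self):
        assert jukes_cantor(0.3) == pytest.approx(-0.75 * math.log(0.6))

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            jukes_cantor(0.75)

    @given(st.floats(min_value=1e-6, max_value=0.74))
    @settings(max_examples=50, deadline=None)
    def test_correction_exceeds_proportion(self, p):
        d = jukes_cantor(p)
        assert d >= p
        assert jukes_cantor(1e-9) == pytest.approx(1e-9, rel=1e-3)


class TestNeiGojobori:
    def test_identical_sequences(self):
        pd = nei_gojobori_pair("ATGGCT", "ATGGCT")
        assert pd.syn_diffs == 0 and pd.nonsyn_diffs == 0
        assert pd.ks == 0 and pd.ka == 0

    def test_phe_leu_example(self):
        # TTT has 1/3 synonymous site (third position); TTT->TTA is nonsynonymous
        pd = nei_gojobori_pair("TTT", "TTA")
        assert pd.syn_diffs == 0 and pd.nonsyn_diffs == 1
        assert oracles.ng_sites_direct("TTT") == pytest.approx(1 / 3)

    def test_site_counts_sum_to_three_per_codon(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            seq_a = "".join(rng.choice(CODONS, 5))
            seq_b = "".join(rng.choice(CODONS, 5))
            pd = nei_gojobori_pair(seq_a, seq_b)
            assert pd.syn_sites + pd.nonsyn_sites == pytest.approx(3 * pd.n_codons)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            seq_a = "".join(rng.choice(CODONS, 6))
            seq_b = "".join(rng.choice(CODONS, 6))
            ab = nei_gojobori_pair(seq_a, seq_b)
            ba = nei_gojobori_pair(seq_b, seq_a)
            assert ab.syn_diffs == pytest.approx(ba.syn_diffs)
            assert ab.nonsyn_diffs == pytest.approx(ba.nonsyn_diffs)
            assert ab.syn_sites == pytest.approx(ba.syn_sites)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(40):
            ca, cb = rng.choice(CODONS, 2)
            pd = nei_gojobori_pair(ca, cb)
            sd, nd = oracles.ng_diffs_direct(ca, cb)
            assert pd.syn_diffs == pytest.approx(sd)
            assert pd.nonsyn_diffs == pytest.approx(nd)
            expect_s = 0.5 * (oracles.ng_sites_direct(ca) +
                              oracles.ng_sites_direct(cb))
            assert pd.syn_sites == pytest.approx(expect_s)

    def test_gapped_codons_excluded_pairwise(self):
        pd = nei_gojobori_pair("ATG-CTGGG", "ATGGCTGGG")
        assert pd.n_codons == 2


class TestDivergenceBetweenGroups:
    CMAP = CodingMap(((1, 9),))

    def test_identical_groups_zero(self):
        aln = make_aln(["ATGGCTAAA"] * 4, paralogs=["p1", "p1", "p2", "p2"])
        for mode in ("fixed_only", "mean_pairwise"):
            pd = divergence_between_groups(aln, self.CMAP, ("pop1", "p1"),
                                           ("pop1", "p2"), mode)
            assert pd.ks == 0 and pd.ka == 0

    def test_polymorphic_site_contributes_nothing_when_fixed_only(self):
        # third-position polymorphism inside p1 only
        aln = make_aln(["ATGGCTAAA", "ATGGCCAAA", "ATGGCTAAA", "ATGGCTAAA"],
                       paralogs=["p1", "p1", "p2", "p2"])
        pd = divergence_between_groups(aln, self.CMAP, ("pop1", "p1"),
                                       ("pop1", "p2"), "fixed_only")
        assert pd.syn_diffs == 0 and pd.nonsyn_diffs == 0

    def test_planted_fixed_synonymous_differences(self):
        # 30 codons; plant 3 fixed synonymous third-position differences
        rng = np.random.default_rng(3)
        codons = list(rng.choice(["ATG", "GCT", "AAA", "CCT", "GGA", "TCC"], 30))
        seq_a = "".join(codons)
        b_codons = list(codons)
        swaps = {"GCT": "GCC", "CCT": "CCC", "GGA": "GGG"}
        planted = 0
        for i, c in enumerate(b_codons):
            if planted < 3 and c in swaps:
                b_codons[i] = swaps[c]
                planted += 1
        assert planted == 3
        seq_b = "".join(b_codons)
        aln = make_aln([seq_a, seq_a, seq_b, seq_b],
                       paralogs=["p1", "p1", "p2", "p2"])
        cmap = CodingMap(((1, 90),))
        pd = divergence_between_groups(aln, cmap, ("pop1", "p1"),
                                       ("pop1", "p2"), "fixed_only")
        sd = sum(oracles.ng_diffs_direct(a, b)[0]
                 for a, b in zip(codons, b_codons))
        nd = sum(oracles.ng_diffs_direct(a, b)[1]
                 for a, b in zip(codons, b_codons))
        assert pd.syn_diffs == pytest.approx(sd) == 3
        assert pd.nonsyn_diffs == pytest.approx(nd) == 0


class TestPiByClass:
    def test_all_identical(self):
        aln = make_aln(["ATGGCT"] * 4)
        s = pi_by_class(aln, CodingMap(((1, 6),)), ("pop1", "p1"))
        assert s.pi_syn == 0 and s.pi_nonsyn == 0
        assert s.s_syn == 0 and s.s_nonsyn == 0

    def test_noncoding_ladder_example(self):
        # 4 haplotypes AAAA/AAAT/AATT/ATTT: 10 pairwise diffs over 6 pairs,
        # 4 sites -> pi = (10/6)/4; S = 3
        aln = make_aln(["AAAA", "AAAT", "AATT", "ATTT"])
        s = pi_by_class(aln, None, ("pop1", "p1"))
        assert s.pi_silent == pytest.approx((10 / 6) / 4)
        assert s.s_silent == 3
        assert s.pi_silent == pytest.approx(oracles.pi_direct(
            ["AAAA", "AAAT", "AATT", "ATTT"]))

    def test_doubling_haplotypes_changes_pi_by_o_one_over_n(self):
        rows = ["AAAA", "AAAT", "AATT", "ATTT"]
        s1 = pi_by_class(make_aln(rows), None, ("pop1", "p1"))
        s2 = pi_by_class(make_aln(rows + rows,), None, ("pop1", "p1"))
        # pi is unnormalised by n/(n-1); doubling shifts it by O(1/n)
        assert abs(s1.pi_silent - s2.pi_silent) < 1.0 / len(rows)
        assert s2.pi_silent == pytest.approx(oracles.pi_direct(rows + rows))

    def test_synonymous_vs_nonsynonymous_partition(self):
        # GCT/GCC synonymous at site 6; ATG/CTG nonsynonymous at site 1
        aln = make_aln(["ATGGCT", "ATGGCC", "CTGGCT", "ATGGCT"])
        s = pi_by_class(aln, CodingMap(((1, 6),)), ("pop1", "p1"))
        assert s.s_syn == 1
        assert s.s_nonsyn == 1

    def test_undefined_tajima_flagged_not_zero(self):
        aln = make_aln(["AAAA"] * 5)
        s = pi_by_class(aln, None, ("pop1", "p1"))
        assert math.isnan(s.tajima_d)


class TestTajimaD:
    def test_worked_value(self):
        assert tajima_d(4, 3, 10 / 6) == pytest.approx(0.17, abs=0.005)
        assert tajima_d(4, 3, 10 / 6) == pytest.approx(
            oracles.tajima_d_direct(4, 3, 10 / 6))

    def test_zero_when_k_equals_watterson(self):
        a1 = sum(1 / i for i in range(1, 7))
        assert tajima_d(7, 5, 5 / a1) == pytest.approx(0.0)

    @pytest.mark.parametrize("n,S", [(3, 5), (10, 0)])
    def test_undefined_cases_flagged(self, n, S):
        assert math.isnan(tajima_d(n, S, 1.0))

    def test_matches_oracle_on_grid(self):
        for n in (4, 8, 15):
            for S in (1, 5, 20):
                for k in (0.5, 2.0, 7.5):
                    assert tajima_d(n, S, k) == pytest.approx(
                        oracles.tajima_d_direct(n, S, k))


class TestSlidingDxy:
    def test_identical_groups_all_zero(self):
        aln = make_aln(["ACGT" * 30] * 4, paralogs=["p1", "p1", "p2", "p2"])
        prof = sliding_dxy(aln, ("pop1", "p1"), ("pop1", "p2"), 60, 12)
        assert np.allclose(prof.dxy, 0.0)

    def test_saturated_window(self):
        aln = make_aln(["A" * 60, "A" * 60, "T" * 60, "T" * 60],
                       paralogs=["p1", "p1", "p2", "p2"])
        prof = sliding_dxy(aln, ("pop1", "p1"), ("pop1", "p2"), 60, 12)
        assert prof.dxy.tolist() == [1.0]

    def test_planted_divergent_block_peaks(self):
        base = "A" * 300
        other = "A" * 120 + "T" * 30 + "A" * 150
        aln = make_aln([base, base, other, other],
                       paralogs=["p1", "p1", "p2", "p2"])
        prof = sliding_dxy(aln, ("pop1", "p1"), ("pop1", "p2"), 30, 10)
        peak = np.nanargmax(prof.dxy)
        assert 121 <= prof.midpoints[peak] <= 150
        assert prof.dxy[0] == 0.0 and prof.dxy[-1] == 0.0
        # every window agrees with the brute-force oracle
        for w in range(len(prof.starts)):
            expect = oracles.dxy_direct([base, base], [other, other],
                                        prof.starts[w] - 1, prof.ends[w])
            assert prof.dxy[w] == pytest.approx(expect)

    def test_single_window_equals_global(self):
        rng = np.random.default_rng(4)
        rows = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(6)]
        aln = make_aln(rows, paralogs=["p1"] * 3 + ["p2"] * 3)
        prof = sliding_dxy(aln, ("pop1", "p1"), ("pop1", "p2"), 50, 1)
        assert prof.dxy[0] == pytest.approx(
            global_dxy(aln, ("pop1", "p1"), ("pop1", "p2")))

    def test_no_ragged_final_window(self):
        aln = make_aln(["ACGT" * 20] * 4, paralogs=["p1", "p1", "p2", "p2"])
        prof = sliding_dxy(aln, ("pop1", "p1"), ("pop1", "p2"), 30, 12)
        assert (prof.ends <= aln.length).all()
        assert np.all(np.diff(prof.starts) == 12)

    def test_all_missing_window_is_nan_not_zero(self):
        aln = make_aln(["--AAAAAAAAAA", "--AAAAAAAAAA",
                        "NNAAAAAAAAAA", "NNAAAAAAAAAA"],
                       paralogs=["p1", "p1", "p2", "p2"])
        prof = sliding_dxy(aln, ("pop1", "p1"), ("pop1", "p2"), 2, 2,
                           min_sites=0)
        assert math.isnan(prof.dxy[0])


class TestColumnEntropy:
    def test_reference_values(self):
        h = column_entropy(["AAAA", "AAAG", "ARAC", "ARAW"])
        # col0 monomorphic; col1 50/50; col3 four equal residues
        assert h[0] == pytest.approx(0.0)
        assert h[1] == pytest.approx(1.0)
        assert h[3] == pytest.approx(2.0)

    def test_all_gap_column_is_nan(self):
        h = column_entropy(["-A", "-A"])
        assert math.isnan(h[0])


class TestOracleEquivalence:
    """Statistics match independent brute force exactly on small alignments."""

    def test_random_small_alignments(self):
        rng = np.random.default_rng(5)
        for rep in range(10):
            n = int(rng.integers(4, 9))
            L = int(rng.integers(12, 61))
            rows = ["".join(rng.choice(list("ACGT"), L)) for _ in range(n)]
            aln = make_aln(rows)
            s = pi_by_class(aln, None, ("pop1", "p1"))
            assert s.pi_silent == pytest.approx(oracles.pi_direct(rows))
            assert s.s_silent == oracles.seg_sites_direct(rows)
            expect_d = oracles.tajima_d_direct(
                n, oracles.seg_sites_direct(rows),
                oracles.mean_pairwise_k_direct(rows))
            assert s.tajima_d == pytest.approx(expect_d)
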