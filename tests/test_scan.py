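import itertools

import numpy as np
import pytest

import oracles
from concerted import (
    AlignmentError,
    ConversionFragment,
    classify_and_cluster,
    minimum_event_counts,
    pair_fragments,
    permutation_pvalues,
    project_polymorphic,
    scan_population,
)
from concerted.simulate import PlantedTract, SimConfig, simulate_dataset
from conftest import make_aln

PARA = ["p1", "p1", "p2", "p2"]


class TestProjection:
    def test_monomorphic_alignment_empty_projection(self):
        proj = project_polymorphic(make_aln(["ACGT" * 5] * 4, paralogs=PARA),
                                   "pop1")
        assert proj.n_sites == 0

    def test_single_variable_column(self):
        rows = ["AAAA", "AAAA", "AAAT", "AAAA"]
        proj = project_polymorphic(make_aln(rows, paralogs=PARA), "pop1")
        assert proj.n_sites == 1
        assert permutation_pvalues(proj, n_perm=10, seed=0) == []

    def test_planted_columns_keep_original_coordinates(self):
        rng = np.random.default_rng(0)
        base = list("A" * 300)
        cols = sorted(rng.choice(300, 10, replace=False))
        rows = []
        for k in range(4):
            r = list(base)
            if k % 2:
                for c in cols:
                    r[c] = "T"
            rows.append("".join(r))
        proj = project_polymorphic(make_aln(rows, paralogs=PARA), "pop1")
        assert proj.columns.tolist() == [c + 1 for c in cols]

    def test_gapped_columns_dropped(self):
        rows = ["A-CT", "AACT", "AACA", "AACT"]
        proj = project_polymorphic(make_aln(rows, paralogs=PARA), "pop1")
        assert proj.columns.tolist() == [4]

    def test_fewer_than_four_sequences_rejected(self):
        with pytest.raises(AlignmentError, match="need"):
            project_polymorphic(make_aln(["AT", "AA", "TA"],
                                         paralogs=["p1", "p1", "p2"]), "pop1")


def _projection_for_pattern(pattern: str):
    """Build a projection where h1 vs h3 follows the match(M)/mismatch(X)
    pattern at the polymorphic sites."""
    top = "".join("A" for _ in pattern)
    bot = "".join("A" if ch == "M" else "T" for ch in pattern)
    # h2/h4 create polymorphism at every column without affecting h1 vs h3
    filler = "".join("C" for _ in pattern)
    rows = [top, filler, bot, filler.replace("C", "G")]
    return project_polymorphic(make_aln(rows, paralogs=PARA), "pop1")


class TestPairFragments:
    def test_full_match_single_fragment(self):
        proj = _projection_for_pattern("MMMMM")
        frags = pair_fragments(proj, "h1", "h3")
        assert len(frags) == 1
        assert (frags[0].start, frags[0].end) == (1, 5)
        assert frags[0].n_poly_sites == 5

    def test_runs_split_at_mismatch_with_counts(self):
        frags = pair_fragments(_projection_for_pattern("MMXMMM"), "h1", "h3",
                               g=0.0, score="count")
        assert [f.score for f in frags] == [2.0, 3.0]
        assert [(f.start, f.end) for f in frags] == [(1, 2), (4, 6)]

    def test_large_penalty_equals_zero_penalty(self):
        a = pair_fragments(_projection_for_pattern("MMXMMM"), "h1", "h3",
                           g=0.0, score="count")
        b = pair_fragments(_projection_for_pattern("MMXMMM"), "h1", "h3",
                           g=100.0, score="count")
        assert [(f.start, f.end, f.score) for f in a] == \
               [(f.start, f.end, f.score) for f in b]

    def test_single_site_fragments_discarded(self):
        frags = pair_fragments(_projection_for_pattern("MXMXM"), "h1", "h3",
                               score="count")
        assert frags == []

    def test_inter_vs_intra_category(self):
        proj = _projection_for_pattern("MMMM")
        inter = pair_fragments(proj, "h1", "h3")
        intra = pair_fragments(proj, "h2", "h4")
        assert inter[0].category == "inter_paralog"
        assert intra == [] or intra[0].category == "intra_paralog"


class TestPermutationPvalues:
    def test_unbeaten_max_gets_minimum_pvalue(self):
        # one pair matches at every polymorphic site: no permutation can beat
        # its score, only tie it; with ties counted, sim_p = 1 when the top
        # pair's fragment is permutation-invariant, so use a pattern whose
        # observed arrangement is strictly best
        proj = _projection_for_pattern("MMMMMMMMMM")
        frags = permutation_pvalues(proj, n_perm=999, seed=1, score="count")
        best = min(f.sim_p for f in frags)
        # the all-match pair ties under every permutation -> sim_p = 1 for it
        full = [f for f in frags if f.n_poly_sites == 10]
        assert full and full[0].sim_p == pytest.approx(1.0)
        assert best >= 1 / 1000

    def test_split_run_is_rarely_reassembled(self):
        # h1/h3 match at 12 consecutive sites out of 24; the permutation
        # must reassemble the run to tie it
        pattern = "M" * 12 + "X" * 12
        proj = _projection_for_pattern(pattern)
        frags = permutation_pvalues(proj, n_perm=999, seed=2, score="count")
        long = [f for f in frags if f.n_poly_sites == 12]
        assert long and long[0].sim_p < 0.05

    def test_exhaustive_enumeration_matches(self):
        # 6 polymorphic columns: compare sampled-path machinery fed with the
        # full 6! enumeration against an independent exhaustive oracle
        proj = _projection_for_pattern("MMMXMX")
        all_perms = np.array(list(itertools.permutations(range(6))))
        frags = permutation_pvalues(proj, perms=all_perms, score="count")
        ids = proj.ids
        pairs = [(ids[a], ids[b]) for a in range(len(ids))
                 for b in range(a + 1, len(ids))]
        match_rows = []
        weights = []
        for si, sj in pairs:
            ia, ib = ids.index(si), ids.index(sj)
            match_rows.append((proj.states[ia] == proj.states[ib]).tolist())
            weights.append(1.0)
        expected = oracles.max_run_pvalue_exhaustive(
            match_rows, [f.score for f in frags], weights)
        for f, e in zip(frags, expected):
            assert f.sim_p == pytest.approx(e)

    def test_seeded_scan_is_reproducible(self):
        proj = _projection_for_pattern("MMXMMMXMMM")
        a = permutation_pvalues(proj, n_perm=200, seed=7)
        b = permutation_pvalues(proj, n_perm=200, seed=7)
        assert [(f.seq_i, f.seq_j, f.score, f.sim_p) for f in a] == \
               [(f.seq_i, f.seq_j, f.score, f.sim_p) for f in b]

    def test_empty_allowed_pairs_rejected(self):
        proj = _projection_for_pattern("MMMM")
        with pytest.raises(AlignmentError):
            permutation_pvalues(proj, allowed_pairs=[], n_perm=10)


def _frag(pop, cat, start, end, p=0.01):
    return ConversionFragment(pop, "a", "b", cat, start, end, 3, 3.0, p)


class TestClustering:
    def test_overlapping_fragments_merge(self):
        clusters = classify_and_cluster(
            [_frag("SD", "inter_paralog", 10, 50),
             _frag("SD", "inter_paralog", 40, 80),
             _frag("SD", "inter_paralog", 100, 120)])
        assert len(clusters) == 2
        assert (clusters[0].start, clusters[0].end) == (10, 80)

    def test_disjoint_fragments_stay_separate(self):
        clusters = classify_and_cluster(
            [_frag("SD", "inter_paralog", 1, 10),
             _frag("SD", "inter_paralog", 20, 30),
             _frag("SD", "inter_paralog", 40, 50)])
        assert len(clusters) == 3

    def test_categories_counted_separately(self):
        clusters = classify_and_cluster(
            [_frag("SD", "inter_paralog", 10, 50),
             _frag("SD", "intra_paralog", 10, 50)])
        counts = minimum_event_counts(clusters)
        assert counts[("SD", "inter_paralog")] == 1
        assert counts[("SD", "intra_paralog")] == 1

    def test_non_significant_fragments_ignored(self):
        clusters = classify_and_cluster(
            [_frag("SD", "inter_paralog", 10, 50, p=0.5)])
        assert clusters == []


class TestScanInvariances:
    def test_record_order_invariance(self):
        cfg = SimConfig(seed=42, n_populations=1, conv_rate=0.0)
        res = simulate_dataset(cfg)
        aln = res.alignment
        shuffled = aln.subset(list(reversed(range(len(aln)))))
        f1, _ = scan_population(aln, "pop1", n_perm=200, seed=3)
        f2, _ = scan_population(shuffled, "pop1", n_perm=200, seed=3)
        key = lambda f: (*sorted((f.seq_i, f.seq_j)), f.start, f.end)
        assert sorted((key(f), f.sim_p) for f in f1) == \
               sorted((key(f), f.sim_p) for f in f2)

    def test_planted_tract_recovered(self):
        planted = (PlantedTract("pop1", "p1", "p2", 451, 750,
                                n_recipient_haplotypes=3),)
        cfg = SimConfig(seed=11, n_populations=1, conv_rate=0.0)
        res = simulate_dataset(cfg, planted)
        frags, clusters = scan_population(res.alignment, "pop1",
                                          n_perm=999, seed=0)
        sig = [f for f in frags
               if f.sim_p < 0.05 and f.category == "inter_paralog"]
        assert any(f.start <= 750 and f.end >= 451 for f in sig)
        counts = minimum_event_counts(clusters)
        assert counts.get(("pop1", "inter_paralog"), 0) >= 1
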