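"""Permutation-based gene-conversion scan (Sawyer statistic).

The scan condenses an alignment to its polymorphic sites, finds, for every
allowed pair of sequences, maximal stretches over which the pair is
identical at those sites ("inner fragments"), and asks whether the best
fragment is longer than expected when the polymorphic columns are randomly
reordered.  Because entire columns are shuffled, each pair's overall match
fraction is preserved under the null, and the permutation distribution of
the maximum fragment score across all allowed pairs yields family-wise
("global") p-values without a separate multiple-testing step.

Fragment scores
---------------
Two scorings are available.  ``"count"`` scores a fragment by its number of
matching polymorphic sites — the textbook statistic.  The default,
``"weighted"``, scores each matching site by −ln(q̂) where q̂ is the pair's
(smoothed) match fraction at polymorphic sites, so a run of matches is worth
more for a dissimilar pair than for a near-identical one.  With group
structure (paralogs), allowed pairs span a wide range of similarities:
intra-paralog pairs match at ~95 % of polymorphic sites and produce long
runs even under the null, so a raw count maximum is dominated by them and a
converted inter-paralog fragment can never reach significance.  The
pair-adaptive weighting makes fragment scores comparable across pairs and
is what gives the scan its power in the duplicated-gene setting.

Group structure mirrors the population × paralog design: conversion is only
searched within populations, with fragments classified as inter- or
intra-paralog by the pair's paralog labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .alignment import GAP, AlignmentError, GroupedAlignment

logger = logging.getLogger(__name__)

#: effective −infinity for the "no mismatches allowed" (g = 0) scoring
_NEG = -1e30


@dataclass
class Projection:
    """Polymorphic-site projection of one population's sequences.

    ``columns`` are 1-based alignment coordinates of the retained sites;
    ``states`` is the (n_sequences, n_sites) base matrix restricted to them.
    """

    population: str
    ids: list[str]
    paralogs: list[str]
    columns: np.ndarray
    states: np.ndarray

    @property
    def n_sites(self) -> int:
        return int(self.columns.size)


@dataclass
class ConversionFragment:
    """A candidate conversion tract between two sequences of one population."""

    population: str
    seq_i: str
    seq_j: str
    category: str  # "inter_paralog" | "intra_paralog"
    start: int  # 1-based alignment column of first supporting site
    end: int  # 1-based alignment column of last supporting site
    n_poly_sites: int  # matching polymorphic sites in the fragment
    score: float
    sim_p: float | None = None


@dataclass
class EventCluster:
    """Overlap-connected component of significant fragments of one
    (population, category); the minimum-event counting unit."""

    population: str
    category: str
    start: int
    end: int
    fragments: list[ConversionFragment] = field(default_factory=list)


def project_polymorphic(aln: GroupedAlignment, population: str) -> Projection:
    """Condense one population's sequences to their polymorphic columns.

    Columns containing a gap or N in any in-scope sequence are excluded (a
    column is droppable, never a match).  Original 1-based coordinates are
    preserved.  Requires ≥ 4 sequences in scope.
    """
    rows = aln.group_indices(population=population)
    if len(rows) < 4:
        raise AlignmentError(
            f"population {population!r} has {len(rows)} sequences; need ≥ 4"
        )
    sub = aln.matrix[rows]
    clean = ~((sub >= GAP).any(axis=0))
    poly = np.zeros(aln.length, dtype=bool)
    idx = np.nonzero(clean)[0]
    for j in idx:
        poly[j] = np.unique(sub[:, j]).size >= 2
    cols = np.nonzero(poly)[0]
    if cols.size < 2:
        logger.warning(
            "population %s has %d polymorphic columns; scan will be skipped",
            population, cols.size,
        )
    return Projection(
        population=population,
        ids=[aln.records[i].haplotype_id for i in rows],
        paralogs=[aln.records[i].paralog for i in rows],
        columns=cols + 1,
        states=sub[:, cols],
    )


# -- fragment extraction ---------------------------------------------------


def _maximal_segments(values: np.ndarray) -> list[tuple[int, int, float]]:
    """All maximal positive-scoring subsequences (Ruzzo–Tompa).

    Returns (start_index, end_index, score) triples, 0-based inclusive.
    """
    out: list[tuple[int, int, float]] = []
    # stack of candidate segments as [L, R, left_prefix, right_prefix]
    stack: list[list[float]] = []
    prefix = 0.0
    for i, v in enumerate(values):
        left = prefix
        prefix += v
        if v <= 0:
            continue
        cur = [i, i, left, prefix]
        while stack:
            # find rightmost segment with left_prefix < cur's left_prefix
            top = stack[-1]
            if top[2] >= cur[2]:
                # dominated: pop and report
                out.append((int(top[0]), int(top[1]), top[3] - top[2]))
                stack.pop()
                continue
            if top[3] >= cur[3]:
                break
            # merge
            cur = [top[0], cur[1], top[2], cur[3]]
            stack.pop()
        stack.append(cur)
    for seg in stack:
        out.append((int(seg[0]), int(seg[1]), seg[3] - seg[2]))
    out.sort()
    return out


def _pair_weight(match: np.ndarray, score: str) -> float:
    """Per-matching-site score contribution for one pair."""
    if score == "count":
        return 1.0
    if score == "weighted":
        c = match.size
        q = (match.sum() + 1.0) / (c + 2.0)  # smoothed match fraction < 1
        return float(-np.log(q))
    raise ValueError(f"unknown score {score!r}")


def pair_fragments(projection: Projection, seq_i: str, seq_j: str,
                   g: float = 0.0, score: str = "count",
                   ) -> list[ConversionFragment]:
    """Candidate fragments for one sequence pair.

    With the default mismatch penalty ``g = 0``, fragments are maximal runs
    of consecutive polymorphic sites at which the pair is identical,
    terminated by any mismatch; with ``g > 0`` they are maximal-scoring
    segments in which each mismatch costs ``g`` match units.  Fragments
    supported by fewer than 2 matching sites are discarded.
    """
    ia = projection.ids.index(seq_i)
    ib = projection.ids.index(seq_j)
    match = projection.states[ia] == projection.states[ib]
    if match.size == 0:
        return []
    w = _pair_weight(match, score)
    if g > 0:
        segments = _maximal_segments(np.where(match, w, -g * w))
    else:
        # maximal runs of matches, terminated by any mismatch
        segments = []
        run_start = None
        for idx in range(match.size + 1):
            if idx < match.size and match[idx]:
                if run_start is None:
                    run_start = idx
            elif run_start is not None:
                segments.append((run_start, idx - 1, (idx - run_start) * w))
                run_start = None
    category = ("intra_paralog"
                if projection.paralogs[ia] == projection.paralogs[ib]
                else "inter_paralog")
    frags = []
    for s, e, sc in segments:
        n_match = int(match[s : e + 1].sum())
        if n_match < 2:
            continue
        frags.append(
            ConversionFragment(
                population=projection.population,
                seq_i=seq_i,
                seq_j=seq_j,
                category=category,
                start=int(projection.columns[s]),
                end=int(projection.columns[e]),
                n_poly_sites=n_match,
                score=float(sc),
            )
        )
    return frags


def _perm_max_scores(values: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Max maximal-segment score over all pairs for each permutation.

    ``values`` is the (n_pairs, n_sites) per-site score matrix; ``perms``
    is (n_perm, n_sites) of column orders.  Kadane's recurrence is run
    column-wise, vectorised over pairs × permutations.
    """
    n_perm = perms.shape[0]
    P, C = values.shape
    best = np.zeros(n_perm)
    chunk = max(1, int(2_000_000 // max(P * C, 1)))
    for lo in range(0, n_perm, chunk):
        pp = perms[lo : lo + chunk]
        v = values[:, pp]  # (P, chunk, C)
        cur = np.zeros((P, pp.shape[0]))
        b = np.zeros(pp.shape[0])
        for c in range(C):
            cur = np.maximum(0.0, cur + v[:, :, c])
            m = cur.max(axis=0)
            b = np.maximum(b, m)
        best[lo : lo + pp.shape[0]] = b
    return best


def permutation_pvalues(projection: Projection,
                        allowed_pairs: Sequence[tuple[str, str]] | None = None,
                        n_perm: int = 10000, seed: int = 0,
                        g: float = 0.0, score: str = "weighted",
                        perms: np.ndarray | None = None,
                        ) -> list[ConversionFragment]:
    """Observed fragments for all allowed pairs with global permutation
    p-values.

    For each permutation the polymorphic columns are shuffled (states move
    together as columns) and the maximum fragment score over all allowed
    pairs recorded; a fragment's global ``sim_p`` is
    ``(1 + #{permutation max ≥ observed score}) / (n_perm + 1)``.

    ``allowed_pairs`` defaults to all pairs of in-scope sequences (the
    within-population design).  An explicit (n_perm, n_sites) array of
    column orders may be supplied via ``perms`` (e.g. the exhaustive
    enumeration for tiny projections), overriding the sampled ones.
    """
    if allowed_pairs is None:
        ids = projection.ids
        allowed_pairs = [(ids[a], ids[b])
                         for a in range(len(ids)) for b in range(a + 1, len(ids))]
    if not allowed_pairs:
        raise AlignmentError("allowed_pairs is empty")
    if projection.n_sites < 2:
        return []

    fragments: list[ConversionFragment] = []
    value_rows = []
    for si, sj in allowed_pairs:
        fragments.extend(pair_fragments(projection, si, sj, g=g, score=score))
        ia, ib = projection.ids.index(si), projection.ids.index(sj)
        match = projection.states[ia] == projection.states[ib]
        w = _pair_weight(match, score)
        value_rows.append(np.where(match, w, -g * w if g > 0 else _NEG))
    values = np.asarray(value_rows)

    C = projection.n_sites
    if perms is None:
        rng = np.random.default_rng(seed)
        perms = np.argsort(rng.random((n_perm, C)), axis=1)
    else:
        perms = np.asarray(perms)
        n_perm = perms.shape[0]
    perm_max = _perm_max_scores(values, perms)
    perm_sorted = np.sort(perm_max)
    for frag in fragments:
        n_ge = len(perm_sorted) - np.searchsorted(
            perm_sorted, frag.score - 1e-9, side="left"
        )
        frag.sim_p = (1.0 + float(n_ge)) / (n_perm + 1.0)
    return fragments


def classify_and_cluster(fragments: Iterable[ConversionFragment],
                         alpha: float = 0.05) -> list[EventCluster]:
    """Merge significant fragments into non-overlapping event clusters.

    Fragments with ``sim_p < alpha`` are grouped by (population, category);
    overlap-connected components are merged, and the number of clusters per
    group is the reported minimum number of conversion events.
    """
    sig = [f for f in fragments
           if f.sim_p is not None and f.sim_p < alpha]
    clusters: list[EventCluster] = []
    keyfun = lambda f: (f.population, f.category)
    for key in sorted({keyfun(f) for f in sig}):
        members = sorted((f for f in sig if keyfun(f) == key),
                         key=lambda f: (f.start, f.end))
        cur: EventCluster | None = None
        for f in members:
            if cur is not None and f.start <= cur.end:
                cur.end = max(cur.end, f.end)
                cur.fragments.append(f)
            else:
                cur = EventCluster(key[0], key[1], f.start, f.end, [f])
                clusters.append(cur)
    return clusters


def minimum_event_counts(clusters: Iterable[EventCluster],
                         ) -> dict[tuple[str, str], int]:
    """Cluster counts per (population, category) — the minimum number of
    distinct gene conversion events consistent with the fragment calls."""
    out: dict[tuple[str, str], int] = {}
    for cl in clusters:
        key = (cl.population, cl.category)
        out[key] = out.get(key, 0) + 1
    return out


def scan_population(aln: GroupedAlignment, population: str,
                    n_perm: int = 10000, seed: int = 0, alpha: float = 0.05,
                    g: float = 0.0, score: str = "weighted",
                    ) -> tuple[list[ConversionFragment], list[EventCluster]]:
    """Full scan of one population: project, score, permute, cluster."""
    proj = project_polymorphic(aln, population)
    if proj.n_sites < 2:
        return [], []
    frags = permutation_pvalues(proj, n_perm=n_perm, seed=seed, g=g, score=score)
    return frags, classify_and_cluster(frags, alpha=alpha)


def scan_all_populations(aln: GroupedAlignment, n_perm: int = 10000,
                         seed: int = 0, alpha: float = 0.05, g: float = 0.0,
                         score: str = "weighted",
                         ) -> tuple[list[ConversionFragment], list[EventCluster]]:
    """Scan every population separately (conversion is only searched within
    populations); per-population seeds are derived deterministically."""
    fragments: list[ConversionFragment] = []
    clusters: list[EventCluster] = []
    for k, pop in enumerate(aln.populations()):
        sub_seed = int(np.random.SeedSequence(seed, spawn_key=(k,)).generate_state(1)[0]
                       % (2**31))
        try:
            fr, cl = scan_population(aln, pop, n_perm=n_perm, seed=sub_seed,
                                     alpha=alpha, g=g, score=score)
        except AlignmentError as exc:
            logger.warning("skipping population %s: %s", pop, exc)
            continue
        fragments.extend(fr)
        clusters.extend(cl)
    return fragments, clusters
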