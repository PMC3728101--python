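"""Polymorphism and divergence statistics for grouped alignments.

Implements the classic descriptive toolbox for duplicated-gene data sets:

* Nei–Gojobori (proportion) synonymous/nonsynonymous divergence with
  Jukes–Cantor correction (``k_s``, ``k_a``, ``k_a/k_s``);
* nucleotide diversity π partitioned into synonymous, nonsynonymous and
  silent (synonymous + noncoding) site classes, with segregating-site
  counts per class;
* Tajima's D;
* sliding-window between-group divergence D_xy;
* per-column Shannon entropy of protein alignments.

π is Nei's estimator (mean pairwise differences per comparable site,
without the n/(n−1) small-sample rescaling), matching the conventions of
the standard polymorphism software these tables are usually produced with.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _codon
from .alignment import (
    GAP,
    NMISS,
    AlignmentError,
    CodingMap,
    GroupedAlignment,
)


class SaturationError(ValueError):
    """Jukes–Cantor correction undefined: proportion of differences ≥ 3/4."""


def jukes_cantor(p: float) -> float:
    """JC69 distance d = −(3/4)·ln(1 − 4p/3); requires 0 ≤ p < 3/4."""
    if p < 0:
        raise ValueError("negative difference proportion")
    if p >= 0.75:
        raise SaturationError(f"p = {p} ≥ 3/4, correction undefined")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


# -- pairwise Nei–Gojobori -------------------------------------------------


@dataclass
class PairwiseDivergence:
    """Nei–Gojobori counts and Jukes–Cantor rates for one comparison."""

    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    n_codons: int

    @property
    def ps(self) -> float:
        return self.syn_diffs / self.syn_sites if self.syn_sites else math.nan

    @property
    def pn(self) -> float:
        return self.nonsyn_diffs / self.nonsyn_sites if self.nonsyn_sites else math.nan

    @property
    def ks(self) -> float:
        return jukes_cantor(self.ps)

    @property
    def ka(self) -> float:
        return jukes_cantor(self.pn)

    @property
    def ratio(self) -> float | None:
        """k_a/k_s, or None when k_s = 0 (printed as '-')."""
        ks = self.ks
        if ks == 0.0:
            return None
        return self.ka / ks


def _clean_codon(cod: str) -> bool:
    return "-" not in cod and "N" not in cod


def nei_gojobori_pair(seq_a: str, seq_b: str, code_table: int = 1) -> PairwiseDivergence:
    """Nei–Gojobori counts between two in-frame nucleotide sequences.

    Codons containing a gap or N in either sequence, and codons that are
    stop codons in either sequence, are excluded pairwise.  Site counts are
    averaged over the two sequences; multi-difference codons are averaged
    over all minimal substitution pathways with equal weight (pathways
    through stop codons excluded).
    """
    if len(seq_a) != len(seq_b):
        raise AlignmentError("sequences differ in length")
    if len(seq_a) % 3:
        raise AlignmentError("sequence length not divisible by 3")
    seq_a = seq_a.upper()
    seq_b = seq_b.upper()
    _, stops = _codon.code_tables(code_table)
    s_sites = 0.0
    sd = nd = 0.0
    used = 0
    for k in range(0, len(seq_a), 3):
        ca, cb = seq_a[k : k + 3], seq_b[k : k + 3]
        if not (_clean_codon(ca) and _clean_codon(cb)):
            continue
        if ca in stops or cb in stops:
            continue
        used += 1
        s_sites += 0.5 * (_codon.syn_sites(ca, code_table) +
                          _codon.syn_sites(cb, code_table))
        d_s, d_n = _codon.pair_diffs(ca, cb, code_table)
        sd += d_s
        nd += d_n
    if used == 0:
        raise AlignmentError("no comparable codons")
    return PairwiseDivergence(
        syn_sites=s_sites,
        nonsyn_sites=3.0 * used - s_sites,
        syn_diffs=sd,
        nonsyn_diffs=nd,
        n_codons=used,
    )


# -- group-level divergence ------------------------------------------------


def _resolve_rows(aln: GroupedAlignment, selector) -> np.ndarray:
    """A group selector is a (population, paralog) tuple or a list of ids."""
    if isinstance(selector, tuple) and len(selector) == 2 and \
            all(isinstance(x, str) for x in selector):
        rows = aln.group_indices(*selector)
    else:
        rows = aln.rows_for_ids(selector)
    if len(rows) == 0:
        raise AlignmentError(f"empty group selector {selector!r}")
    return rows


def _column_consensus(aln: GroupedAlignment, rows: np.ndarray) -> np.ndarray:
    """Per-column majority non-missing state (lexicographic tie-break);
    NMISS where the column is all-missing in the group."""
    sub = aln.matrix[rows]
    out = np.full(aln.length, NMISS, dtype=np.int8)
    for j in range(aln.length):
        col = sub[:, j]
        col = col[col < GAP]
        if col.size == 0:
            continue
        vals, counts = np.unique(col, return_counts=True)
        out[j] = vals[np.argmax(counts)]  # np.unique sorts: ties → smallest base
    return out


def _column_polymorphic(aln: GroupedAlignment, rows: np.ndarray) -> np.ndarray:
    sub = aln.matrix[rows]
    poly = np.zeros(aln.length, dtype=bool)
    for j in range(aln.length):
        col = sub[:, j]
        col = col[col < GAP]
        poly[j] = np.unique(col).size >= 2
    return poly


def divergence_between_groups(aln: GroupedAlignment, cmap: CodingMap,
                              group_a, group_b,
                              mode: str = "fixed_only") -> PairwiseDivergence:
    """Coding divergence between two groups of haplotypes.

    ``fixed_only`` (the convention for "fixed divergence" tables) compares
    group consensus sequences with every site that is polymorphic inside
    either group masked to equality, so only fixed differences contribute;
    ``mean_pairwise`` averages Nei–Gojobori counts over all between-group
    sequence pairs.
    """
    rows_a = _resolve_rows(aln, group_a)
    rows_b = _resolve_rows(aln, group_b)
    cols = cmap.coding_columns()
    if mode == "fixed_only":
        cons_a = _column_consensus(aln, rows_a)
        cons_b = _column_consensus(aln, rows_b)
        poly = _column_polymorphic(aln, rows_a) | _column_polymorphic(aln, rows_b)
        a = cons_a.copy()
        b = cons_b.copy()
        mask = poly & (a < GAP) & (b < GAP)
        b[mask] = a[mask]  # polymorphic sites contribute sites but no differences
        from .alignment import ALPHABET

        seq_a = "".join(ALPHABET[a[c - 1]] for c in cols)
        seq_b = "".join(ALPHABET[b[c - 1]] for c in cols)
        return nei_gojobori_pair(seq_a, seq_b, cmap.code_table)
    if mode == "mean_pairwise":
        tot = np.zeros(4)
        n_codons = 0
        n_pairs = 0
        for i in rows_a:
            res_i = "".join(aln.records[i].residues[c - 1] for c in cols)
            for j in rows_b:
                res_j = "".join(aln.records[j].residues[c - 1] for c in cols)
                pd = nei_gojobori_pair(res_i, res_j, cmap.code_table)
                tot += (pd.syn_sites, pd.nonsyn_sites, pd.syn_diffs, pd.nonsyn_diffs)
                n_codons += pd.n_codons
                n_pairs += 1
        tot /= n_pairs
        return PairwiseDivergence(tot[0], tot[1], tot[2], tot[3],
                                  round(n_codons / n_pairs))
    raise ValueError(f"unknown mode {mode!r}")


# -- within-group diversity ------------------------------------------------


@dataclass
class PolymorphismSummary:
    """Per-group diversity by site class (a Table-2-style row)."""

    population: str
    paralog: str
    n_hap: int
    pi_syn: float
    pi_nonsyn: float
    pi_silent: float
    s_syn: int
    s_nonsyn: int
    s_silent: int
    tajima_d: float  # NaN when undefined (S = 0 or n_hap < 4)


def tajima_d(n_hap: int, S: int, mean_pairwise_k: float) -> float:
    """Tajima's D from sample size, segregating sites and mean pairwise
    difference count.  Returns NaN when undefined (S = 0 or n_hap < 4)."""
    if S <= 0 or n_hap < 4:
        return math.nan
    n = n_hap
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1.0)
    return (mean_pairwise_k - S / a1) / math.sqrt(var)


def _classify_coding_site(group_codons: list[list[str]], codon_idx: int,
                          pos_in_codon: int, variants: list[str],
                          code_table: int) -> str | None:
    """'syn'/'nonsyn' classification of a segregating coding site.

    Variant bases are placed in the group's majority clean codon at that
    position; the site is synonymous iff all variant codons translate
    identically (changes to stops count as nonsynonymous).  Returns None
    when no clean background codon exists.
    """
    forward, stops = _codon.code_tables(code_table)
    counts: dict[str, int] = {}
    for seq in group_codons:
        cod = seq[codon_idx]
        if _clean_codon(cod) and cod not in stops:
            counts[cod] = counts.get(cod, 0) + 1
    if not counts:
        return None
    background = max(counts.items(), key=lambda kv: (kv[1], [-ord(c) for c in kv[0]]))[0]
    aas = set()
    for base in variants:
        cod = background[:pos_in_codon] + base + background[pos_in_codon + 1 :]
        aas.add("*" if cod in stops else forward[cod])
    return "syn" if len(aas) == 1 else "nonsyn"


def pi_by_class(aln: GroupedAlignment, cmap: CodingMap | None, group,
                ) -> PolymorphismSummary:
    """Nucleotide diversity and segregating sites by site class for one
    (population, paralog) group.

    Columns with a gap or N anywhere in the group are excluded (listwise).
    π_syn/π_nonsyn use pairwise Nei–Gojobori site and difference counts;
    π_silent pools synonymous and noncoding sites.  Tajima's D is computed
    over all included sites.  With ``cmap=None`` the whole alignment is
    treated as noncoding (π_silent then equals total π).
    """
    rows = _resolve_rows(aln, group)
    if len(rows) < 2:
        raise AlignmentError("need at least 2 haplotypes for diversity")
    if isinstance(group, tuple) and len(group) == 2:
        population, paralog = group
    else:
        population, paralog = "-", "-"
    n = len(rows)
    sub = aln.matrix[rows]
    clean_col = ~(((sub == GAP) | (sub == NMISS)).any(axis=0))  # listwise

    code_table = cmap.code_table if cmap is not None else 1
    if cmap is not None:
        codon_cols = cmap.codon_columns()  # (n_codons, 3) 1-based
        nc_cols = cmap.noncoding_columns(aln.length)
    else:
        codon_cols = np.empty((0, 3), dtype=int)
        nc_cols = np.arange(1, aln.length + 1)
    nc_cols = nc_cols[clean_col[nc_cols - 1]]

    # codons usable listwise: all three columns clean, no stop/ambiguous codon
    _, stops = _codon.code_tables(code_table)
    group_codons: list[list[str]] = []
    for i in rows:
        res = aln.records[i].residues
        group_codons.append(["".join(res[c - 1] for c in codon) for codon in codon_cols])
    usable = []
    for k in range(len(codon_cols)):
        if not clean_col[codon_cols[k] - 1].all():
            continue
        if any(seq[k] in stops for seq in group_codons):
            continue
        usable.append(k)

    # pairwise accumulation
    pair_ps, pair_pn, pair_silent = [], [], []
    nc_mat = sub[:, nc_cols - 1] if nc_cols.size else np.empty((n, 0), dtype=np.int8)
    for ia in range(n):
        for ib in range(ia + 1, n):
            s_sites = sd = nd = 0.0
            for k in usable:
                ca, cb = group_codons[ia][k], group_codons[ib][k]
                s_sites += 0.5 * (_codon.syn_sites(ca, code_table) +
                                  _codon.syn_sites(cb, code_table))
                d_s, d_n = _codon.pair_diffs(ca, cb, code_table)
                sd += d_s
                nd += d_n
            n_sites = 3.0 * len(usable) - s_sites
            nc_d = float((nc_mat[ia] != nc_mat[ib]).sum())
            if s_sites > 0:
                pair_ps.append(sd / s_sites)
            if n_sites > 0:
                pair_pn.append(nd / n_sites)
            if s_sites + nc_cols.size > 0:
                pair_silent.append((sd + nc_d) / (s_sites + nc_cols.size))

    pi_syn = float(np.mean(pair_ps)) if pair_ps else math.nan
    pi_nonsyn = float(np.mean(pair_pn)) if pair_pn else math.nan
    pi_silent = float(np.mean(pair_silent)) if pair_silent else math.nan

    # segregating-site counts by class
    s_syn = s_nonsyn = 0
    for k in usable:
        for p in range(3):
            col = codon_cols[k][p]
            states = sorted({seq[k][p] for seq in group_codons})
            if len(states) < 2:
                continue
            cls = _classify_coding_site(group_codons, k, p, states, code_table)
            if cls == "syn":
                s_syn += 1
            elif cls == "nonsyn":
                s_nonsyn += 1
    s_nc = 0
    for j in range(nc_mat.shape[1]):
        if np.unique(nc_mat[:, j]).size >= 2:
            s_nc += 1
    s_silent = s_syn + s_nc

    # Tajima's D over all included sites
    inc = np.nonzero(clean_col)[0]
    m = sub[:, inc]
    S_total = sum(1 for j in range(m.shape[1]) if np.unique(m[:, j]).size >= 2)
    diffs = [float((m[ia] != m[ib]).sum()) for ia in range(n) for ib in range(ia + 1, n)]
    k_bar = float(np.mean(diffs)) if diffs else 0.0
    d = tajima_d(n, S_total, k_bar)

    return PolymorphismSummary(population, paralog, n, pi_syn, pi_nonsyn,
                               pi_silent, s_syn, s_nonsyn, s_silent, d)


# -- sliding-window divergence ---------------------------------------------


@dataclass
class WindowProfile:
    """Sliding-window D_xy track between two groups.

    One row per window: start, end, midpoint (1-based columns), dxy (NaN
    where no pair has comparable sites), mean number of comparable sites
    across pairs, and a low-confidence flag (< ``min_sites`` comparable)."""

    window: int
    step: int
    label_a: str
    label_b: str
    starts: np.ndarray
    ends: np.ndarray
    midpoints: np.ndarray
    dxy: np.ndarray
    n_sites: np.ndarray
    low_confidence: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "start": self.starts,
                "end": self.ends,
                "mid": self.midpoints,
                "dxy": self.dxy,
                "n_sites": self.n_sites,
                "low_confidence": self.low_confidence,
            }
        )


def sliding_dxy(aln: GroupedAlignment, group_a, group_b, window: int,
                step: int = 1, min_sites: int = 10,
                labels: tuple[str, str] | None = None) -> WindowProfile:
    """Windowed mean pairwise divergence between two groups.

    Per window, D_xy is the mean over all between-group pairs of
    (differences / comparable sites) in the window; sites with a gap or N
    in either member of a pair are excluded for that pair.  Windows are
    emitted while ``start + window − 1 ≤ L`` (no ragged final window).
    """
    if window > aln.length:
        raise AlignmentError("window longer than alignment")
    if step < 1:
        raise ValueError("step must be ≥ 1")
    rows_a = _resolve_rows(aln, group_a)
    rows_b = _resolve_rows(aln, group_b)
    m = aln.matrix
    pair_diff = []
    pair_comp = []
    for i in rows_a:
        for j in rows_b:
            ok = (m[i] < GAP) & (m[j] < GAP)
            pair_comp.append(ok)
            pair_diff.append(ok & (m[i] != m[j]))
    diff = np.asarray(pair_diff)  # (P, L)
    comp = np.asarray(pair_comp)
    cdiff = np.concatenate([np.zeros((diff.shape[0], 1)), np.cumsum(diff, axis=1)], axis=1)
    ccomp = np.concatenate([np.zeros((comp.shape[0], 1)), np.cumsum(comp, axis=1)], axis=1)

    starts = np.arange(1, aln.length - window + 2, step)
    ends = starts + window - 1
    dxy = np.full(len(starts), np.nan)
    nsites = np.zeros(len(starts))
    for w, (s, e) in enumerate(zip(starts, ends)):
        d = cdiff[:, e] - cdiff[:, s - 1]
        c = ccomp[:, e] - ccomp[:, s - 1]
        have = c > 0
        if have.any():
            dxy[w] = float(np.mean(d[have] / c[have]))
        nsites[w] = float(np.mean(c))
    la, lb = labels if labels else (str(group_a), str(group_b))
    return WindowProfile(window, step, la, lb, starts, ends,
                         (starts + ends) / 2.0, dxy, nsites,
                         nsites < min_sites)


def global_dxy(aln: GroupedAlignment, group_a, group_b) -> float:
    """Whole-alignment D_xy (single window spanning all columns)."""
    prof = sliding_dxy(aln, group_a, group_b, window=aln.length, step=1,
                       min_sites=0)
    return float(prof.dxy[0])


# -- protein conservation --------------------------------------------------


def column_entropy(protein_seqs: Sequence[str]) -> np.ndarray:
    """Shannon entropy H (bits) per column of a protein alignment.

    Gaps ('-', '.') and 'X' are excluded; all-missing columns are NaN.
    H = −Σ p_a log2 p_a over observed residues; 0 for monomorphic columns.
    """
    if not protein_seqs:
        raise ValueError("empty protein alignment")
    lengths = {len(s) for s in protein_seqs}
    if len(lengths) != 1:
        raise AlignmentError("protein sequences differ in length")
    L = lengths.pop()
    out = np.full(L, np.nan)
    for j in range(L):
        residues = [s[j].upper() for s in protein_seqs if s[j].upper() not in "-.X"]
        if not residues:
            continue
        _, counts = np.unique(residues, return_counts=True)
        p = counts / counts.sum()
        out[j] = float(-(p * np.log2(p)).sum())
    return out
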