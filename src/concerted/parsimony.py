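"""Parsimony phylogenetics on gene partitions.

Fitch scoring, random-addition + NNI heuristic search, nonparametric
bootstrap with 50 % majority-rule consensus, outgroup rooting, and a
partition-incongruence report used to demonstrate chimeric haplotype
history: when the 5′ and 3′ parts of a gene are analysed separately, a
haplotype created by inter-paralog conversion attaches to a different
paralog clade in each partition tree.

Trees cross the public boundary as :class:`dendropy.Tree` objects (or
Newick strings); gaps and N are scored as missing data (any state).
Nucleotide states are bitmasks (A=1, C=2, G=4, T=8, missing=15) so a Fitch
node update is two vectorised bit operations per column pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .alignment import AlignmentError, GroupedAlignment

logger = logging.getLogger(__name__)

_MASK = np.array([1, 2, 4, 8, 15, 15], dtype=np.uint8)  # A,C,G,T,-,N


@dataclass(frozen=True)
class PartitionSpec:
    """A named 1-based inclusive column interval of the alignment."""

    name: str
    start: int
    end: int

    def check(self, length: int) -> None:
        if not (1 <= self.start <= self.end <= length):
            raise AlignmentError(
                f"partition {self.name!r} ({self.start}..{self.end}) outside 1..{length}"
            )


class CharacterData:
    """Bitmask-encoded, pattern-compressed characters for a set of taxa.

    Taxa are sorted by label so that downstream searches are invariant to
    alignment record order.  Constant and all-missing patterns are dropped
    (they never contribute parsimony length).
    """

    def __init__(self, aln: GroupedAlignment, partition: PartitionSpec | None = None):
        if partition is not None:
            partition.check(aln.length)
            lo, hi = partition.start - 1, partition.end
        else:
            lo, hi = 0, aln.length
        order = sorted(range(len(aln.records)),
                       key=lambda i: aln.records[i].haplotype_id)
        self.taxa: list[str] = [aln.records[i].haplotype_id for i in order]
        masks = _MASK[aln.matrix[order, lo:hi]]
        self.n_columns = hi - lo
        # drop columns where fewer than two distinct real states occur
        keep = []
        for j in range(masks.shape[1]):
            col = masks[:, j]
            real = {int(x) for x in col if x != 15}
            if len(real) >= 2:
                keep.append(j)
        masks = masks[:, keep]
        # pattern compression
        patterns: dict[bytes, int] = {}
        weights: list[int] = []
        cols: list[np.ndarray] = []
        for j in range(masks.shape[1]):
            key = masks[:, j].tobytes()
            if key in patterns:
                weights[patterns[key]] += 1
            else:
                patterns[key] = len(cols)
                cols.append(masks[:, j].copy())
                weights.append(1)
        self.masks = (np.stack(cols, axis=1) if cols
                      else np.empty((len(self.taxa), 0), dtype=np.uint8))
        self.weights = np.asarray(weights, dtype=float)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)


# -- internal unrooted-tree machinery --------------------------------------


class _UTree:
    """Unrooted binary tree over tips 0..n−1 as an adjacency map."""

    __slots__ = ("nbrs", "n_tips", "_next")

    def __init__(self, nbrs: dict[int, list[int]], n_tips: int, next_id: int):
        self.nbrs = nbrs
        self.n_tips = n_tips
        self._next = next_id

    @classmethod
    def star3(cls, a: int, b: int, c: int, n_tips: int) -> "_UTree":
        hub = n_tips
        return cls({a: [hub], b: [hub], c: [hub], hub: [a, b, c]}, n_tips,
                   n_tips + 1)

    def copy(self) -> "_UTree":
        return _UTree({k: list(v) for k, v in self.nbrs.items()},
                      self.n_tips, self._next)

    def edges(self) -> list[tuple[int, int]]:
        out = []
        for u, vs in self.nbrs.items():
            for v in vs:
                if u < v:
                    out.append((u, v))
        return out

    def internal_edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u, v in self.edges()
                if u >= self.n_tips and v >= self.n_tips]

    def insert_tip(self, tip: int, edge: tuple[int, int]) -> None:
        u, v = edge
        w = self._next
        self._next += 1
        self.nbrs[u].remove(v)
        self.nbrs[v].remove(u)
        self.nbrs[u].append(w)
        self.nbrs[v].append(w)
        self.nbrs[w] = [u, v, tip]
        self.nbrs[tip] = [w]

    def nni(self, edge: tuple[int, int], which: int) -> "_UTree":
        """One of the two NNI rearrangements across an internal edge."""
        u, v = edge
        t = self.copy()
        a, b = [x for x in t.nbrs[u] if x != v]
        c, d = [x for x in t.nbrs[v] if x != u]
        swap_u, swap_v = (b, c) if which == 0 else (b, d)
        t.nbrs[u][t.nbrs[u].index(swap_u)] = swap_v
        t.nbrs[v][t.nbrs[v].index(swap_v)] = swap_u
        t.nbrs[swap_u][t.nbrs[swap_u].index(u)] = v
        t.nbrs[swap_v][t.nbrs[swap_v].index(v)] = u
        return t

    def postorder(self) -> tuple[list[tuple[int, int, int]], int, int]:
        """Root on the smallest tip present: returns (internal nodes as
        (node, child1, child2) in postorder, top internal node, root tip)."""
        root = min(k for k in self.nbrs if k < self.n_tips)
        start = self.nbrs[root][0]
        order: list[tuple[int, int, int]] = []
        stack = [(start, root)]
        visit: list[tuple[int, int]] = []
        while stack:
            node, parent = stack.pop()
            visit.append((node, parent))
            for nb in self.nbrs[node]:
                if nb != parent:
                    stack.append((nb, node))
        children: dict[int, list[int]] = {}
        for node, parent in visit[1:]:
            children.setdefault(parent, []).append(node)
        for node, _ in reversed(visit):
            if node >= self.n_tips:
                c = children[node]
                order.append((node, c[0], c[1]))
        return order, start, root

    def bipartitions(self) -> frozenset[frozenset[int]]:
        """Non-trivial tip bipartitions (as the smaller-side frozensets... both
        sides canonicalised by the side not containing tip 0)."""
        out = set()
        for u, v in self.internal_edges():
            side = self._tips_on_side(u, v)
            if 0 in side:
                side = frozenset(range(self.n_tips)) - side
            if 1 < len(side) < self.n_tips - 1:
                out.add(frozenset(side))
        return frozenset(out)

    def _tips_on_side(self, u: int, v: int) -> frozenset[int]:
        """Tips on the v side of edge (u, v)."""
        seen = set()
        stack = [(v, u)]
        while stack:
            node, parent = stack.pop()
            if node < self.n_tips:
                seen.add(node)
            for nb in self.nbrs[node]:
                if nb != parent:
                    stack.append((nb, node))
        return frozenset(seen)

    def newick(self, taxa: Sequence[str]) -> str:
        def sub(node: int, parent: int) -> str:
            if node < self.n_tips:
                return taxa[node]
            parts = sorted(sub(nb, node) for nb in self.nbrs[node] if nb != parent)
            return "(" + ",".join(parts) + ")"

        root = min(k for k in self.nbrs if k < self.n_tips)
        start = self.nbrs[root][0]
        inner = sorted(sub(nb, start) for nb in self.nbrs[start] if nb != root)
        return f"({taxa[root]},{','.join(inner)});"


def _score_tree(tree: _UTree, data: CharacterData) -> float:
    """Weighted Fitch parsimony length of an unrooted tree."""
    if data.masks.shape[1] == 0:
        return 0.0
    order, top, root = tree.postorder()
    node_masks: dict[int, np.ndarray] = {
        i: data.masks[i] for i in range(data.n_taxa)
    }
    cost = 0.0
    for node, c1, c2 in order:
        m1, m2 = node_masks[c1], node_masks[c2]
        inter = m1 & m2
        zero = inter == 0
        if zero.any():
            cost += data.weights[zero].sum()
        node_masks[node] = np.where(zero, m1 | m2, inter)
    final = node_masks[top] & node_masks[root]
    cost += data.weights[final == 0].sum()
    return float(cost)


def _tree_from_newick(newick: str, taxa: Sequence[str]) -> _UTree:
    """Parse a Newick string (via dendropy) into the internal representation."""
    dt = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return _tree_from_dendropy(dt, taxa)


def _tree_from_dendropy(dt: dendropy.Tree, taxa: Sequence[str]) -> _UTree:
    index = {label: i for i, label in enumerate(taxa)}
    n_tips = len(taxa)
    dt = dt.clone(depth=1)
    nbrs: dict[int, list[int]] = {}
    next_internal = [n_tips]

    def walk(node) -> int:
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            if label not in index:
                raise AlignmentError(f"tree tip {label!r} absent from alignment")
            return index[label]
        me = next_internal[0]
        next_internal[0] += 1
        nbrs.setdefault(me, [])
        for ch in node.child_nodes():
            cid = walk(ch)
            nbrs[me].append(cid)
            nbrs.setdefault(cid, []).append(me)
        return me

    walk(dt.seed_node)
    # suppress any unifurcation at the seed
    for node, vs in list(nbrs.items()):
        if node >= n_tips and len(vs) == 2:
            a, b = vs
            nbrs[a][nbrs[a].index(node)] = b
            nbrs[b][nbrs[b].index(node)] = a
            del nbrs[node]
    return _UTree(nbrs, n_tips, next_internal[0])


# -- public operations -----------------------------------------------------


def fitch_score(tree, aln: GroupedAlignment,
                partition: PartitionSpec | None = None) -> int:
    """Fitch parsimony length of ``tree`` (dendropy Tree or Newick string)
    on the given partition; gaps/N are missing data."""
    data = CharacterData(aln, partition)
    if isinstance(tree, str):
        ut = _tree_from_newick(tree, data.taxa)
    else:
        ut = _tree_from_dendropy(tree, data.taxa)
    return int(round(_score_tree(ut, data)))


def _search(data: CharacterData, n_starts: int, rng: np.random.Generator,
            collect_ties: bool = True) -> tuple[list[_UTree], float]:
    n = data.n_taxa
    best_score = np.inf
    best: dict[frozenset, _UTree] = {}

    for _ in range(n_starts):
        order = rng.permutation(n)
        t = _UTree.star3(int(order[0]), int(order[1]), int(order[2]), n)
        for tip in order[3:]:
            cand_best = None
            cand_score = np.inf
            for edge in t.edges():
                trial = t.copy()
                trial.insert_tip(int(tip), edge)
                s = _score_tree(trial, data)
                if s < cand_score:
                    cand_score = s
                    cand_best = trial
            t = cand_best
        score = _score_tree(t, data)
        improved = True
        while improved:
            improved = False
            for edge in t.internal_edges():
                for which in (0, 1):
                    trial = t.nni(edge, which)
                    s = _score_tree(trial, data)
                    if s < score - 1e-9:
                        t, score = trial, s
                        improved = True
                        break
                if improved:
                    break
        if score < best_score - 1e-9:
            best_score = score
            best = {t.bipartitions(): t}
        elif abs(score - best_score) <= 1e-9:
            best.setdefault(t.bipartitions(), t)
        if collect_ties:
            for edge in t.internal_edges():
                for which in (0, 1):
                    trial = t.nni(edge, which)
                    if abs(_score_tree(trial, data) - best_score) <= 1e-9:
                        best.setdefault(trial.bipartitions(), trial)
    return list(best.values()), float(best_score)


def search_mp(aln: GroupedAlignment, partition: PartitionSpec | None = None,
              n_starts: int = 10, seed: int = 0,
              ) -> tuple[list[dendropy.Tree], int]:
    """Heuristic maximum-parsimony search: random-addition starting trees
    followed by NNI hill climbing.  Returns all distinct best topologies
    found (equal-score NNI neighbours of final trees included) and the best
    score."""
    data = CharacterData(aln, partition)
    tns = dendropy.TaxonNamespace(data.taxa)
    if data.n_taxa < 4:
        logger.warning("fewer than 4 taxa: returning the trivial topology")
        nwk = "(" + ",".join(data.taxa) + ");"
        t = dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=tns, preserve_underscores=True)
        score = 0 if data.masks.shape[1] == 0 else int(
            data.weights.sum() * 0 + sum(
                data.weights[j] * (len({int(x) for x in data.masks[:, j]
                                        if x != 15}) - 1)
                for j in range(data.masks.shape[1]))
        )
        return [t], score
    rng = np.random.default_rng(seed)
    trees, score = _search(data, n_starts, rng)
    out = [dendropy.Tree.get(data=t.newick(data.taxa), schema="newick",
                             taxon_namespace=tns, preserve_underscores=True) for t in trees]
    return out, int(round(score))


def bootstrap_consensus(aln: GroupedAlignment,
                        partition: PartitionSpec | None = None,
                        n_reps: int = 1000, seed: int = 0,
                        outgroup: str | None = None,
                        n_starts_per_rep: int = 2) -> dendropy.Tree:
    """Parsimony bootstrap and 50 % majority-rule consensus.

    Columns of the partition are resampled with replacement per replicate,
    a reduced search is run, and bipartition frequencies across replicates
    give integer percent supports (stored on node labels and
    ``node.support``).  The consensus is rooted on ``outgroup`` when given.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be ≥ 1")
    data = CharacterData(aln, partition)
    if data.n_taxa < 4:
        raise AlignmentError("bootstrap needs at least 4 taxa")
    if outgroup is not None and outgroup not in data.taxa:
        raise AlignmentError(f"outgroup {outgroup!r} absent from alignment")
    rng = np.random.default_rng(seed)
    base_weights = data.weights.copy()
    n_cols = int(base_weights.sum())
    p = base_weights / n_cols
    counts: dict[frozenset[frozenset[int]], int] = {}
    bip_counts: dict[frozenset[int], int] = {}
    for _ in range(n_reps):
        data.weights = rng.multinomial(n_cols, p).astype(float)
        trees, _score = _search(data, n_starts_per_rep, rng, collect_ties=False)
        tree = trees[0]
        for bip in tree.bipartitions():
            bip_counts[bip] = bip_counts.get(bip, 0) + 1
    data.weights = base_weights

    # 50% majority-rule consensus from bipartition frequencies
    majority = sorted(
        ((bip, c) for bip, c in bip_counts.items() if c * 2 > n_reps),
        key=lambda kv: -len(kv[0]),
    )
    tns = dendropy.TaxonNamespace(data.taxa)
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    tip_nodes = {}
    for i, label in enumerate(data.taxa):
        node = dendropy.Node(taxon=tns.get_taxon(label))
        root.add_child(node)
        tip_nodes[i] = node

    def tips_under(node) -> set[int]:
        return {data.taxa.index(lf.taxon.label) for lf in node.leaf_iter()}

    for bip, c in majority:
        # find the shallowest node whose children cover the bipartition
        holder = root
        moved = True
        while moved:
            moved = False
            for ch in holder.child_nodes():
                if not ch.is_leaf() and bip <= tips_under(ch):
                    holder = ch
                    moved = True
                    break
        group = [ch for ch in holder.child_nodes() if tips_under(ch) <= bip]
        covered = set().union(*(tips_under(ch) for ch in group)) if group else set()
        if covered != set(bip):
            continue  # incompatible with already-placed bipartitions
        new = dendropy.Node()
        support = int(round(100.0 * c / n_reps))
        new.label = str(support)
        new.support = support
        for ch in group:
            holder.remove_child(ch)
            new.add_child(ch)
        holder.add_child(new)

    if outgroup is not None:
        og = tree.find_node_with_taxon_label(outgroup)
        tree.to_outgroup_position(og, update_bipartitions=False,
                                  suppress_unifurcations=True)
    return tree


@dataclass
class IncongruenceReport:
    """Where each focal tip attaches in two partition trees, plus the
    Robinson–Foulds distance between the trees."""

    rf_distance: int
    assignments: dict[str, tuple[str, str]]  # tip -> (clade in A, clade in B)


def _attachment(tree: dendropy.Tree, tip: str, clade_a: set[str],
                clade_b: set[str]) -> str:
    node = tree.find_node_with_taxon_label(tip)
    if node is None:
        raise AlignmentError(f"focal tip {tip!r} absent from tree")
    cur = node.parent_node
    while cur is not None:
        labels = {lf.taxon.label for lf in cur.leaf_iter()} - {tip}
        na = len(labels & clade_a)
        nb = len(labels & clade_b)
        if na or nb:
            if na > nb:
                return "A"
            if nb > na:
                return "B"
            return "ambiguous"
        cur = cur.parent_node
    return "ambiguous"


def partition_incongruence(tree_a: dendropy.Tree, tree_b: dendropy.Tree,
                           focal_tips: Iterable[str],
                           clade_a_def: Iterable[str],
                           clade_b_def: Iterable[str]) -> IncongruenceReport:
    """Compare where putative chimeras attach in two partition trees.

    For each focal tip the nearest surrounding clade (by walking rootward
    until definition members are reached) is reported for both trees, with
    the unrooted Robinson–Foulds distance between the trees.
    """
    labels_a = {lf.taxon.label for lf in tree_a.leaf_node_iter()}
    labels_b = {lf.taxon.label for lf in tree_b.leaf_node_iter()}
    if labels_a != labels_b:
        raise AlignmentError("trees have different tip sets")
    clade_a = set(clade_a_def)
    clade_b = set(clade_b_def)
    for cl in (clade_a, clade_b):
        missing = cl - labels_a
        if missing:
            raise AlignmentError(f"clade definition tips missing from trees: {missing}")

    tns = dendropy.TaxonNamespace(sorted(labels_a))
    ta = dendropy.Tree.get(data=tree_a.as_string(schema="newick", unquoted_underscores=True),
                           schema="newick", taxon_namespace=tns, preserve_underscores=True)
    tb = dendropy.Tree.get(data=tree_b.as_string(schema="newick", unquoted_underscores=True),
                           schema="newick", taxon_namespace=tns, preserve_underscores=True)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    rf = int(dendropy.calculate.treecompare.symmetric_difference(ta, tb))

    assignments = {}
    for tip in focal_tips:
        assignments[tip] = (
            _attachment(tree_a, tip, clade_a, clade_b),
            _attachment(tree_b, tip, clade_a, clade_b),
        )
    return IncongruenceReport(rf_distance=rf, assignments=assignments)
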