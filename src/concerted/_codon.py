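"""Nei–Gojobori codon bookkeeping: synonymous site fractions per codon and
pathway-averaged synonymous/nonsynonymous difference counts per codon pair.

Counting rules (the classic proportion method):

* potential synonymous sites of a codon = sum over the three positions of
  (number of synonymous single-base changes at that position) / 3, with
  changes to stop codons counted as nonsynonymous;
* for a codon pair differing at k positions, the k! substitution orders are
  enumerated, orders passing through a stop codon are discarded, and the
  synonymous/nonsynonymous step counts are averaged with equal weight over
  the remaining orders (over all orders if every order hits a stop).

Tables are computed lazily once per genetic code and cached.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

from Bio.Data.CodonTable import unambiguous_dna_by_id

BASES = "ACGT"


@lru_cache(maxsize=None)
def code_tables(code_table: int = 1):
    """(forward dict codon->aa, set of stop codons) for an NCBI table id."""
    table = unambiguous_dna_by_id[code_table]
    return dict(table.forward_table), frozenset(table.stop_codons)


@lru_cache(maxsize=None)
def syn_sites(codon: str, code_table: int = 1) -> float:
    """Potential synonymous sites of ``codon`` (0..3); nonsynonymous = 3 - s."""
    forward, stops = code_tables(code_table)
    if codon in stops:
        raise ValueError(f"stop codon {codon} has no site counts")
    aa = forward[codon]
    s = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if mutant not in stops and forward[mutant] == aa:
                s += 1.0 / 3.0
    return s


@lru_cache(maxsize=None)
def pair_diffs(codon_a: str, codon_b: str, code_table: int = 1) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two codons,
    averaged over minimal substitution pathways with equal weight.

    Pathways with a stop-codon intermediate are excluded; if all pathways
    pass through a stop, all are used.  Either codon being a stop raises.
    """
    forward, stops = code_tables(code_table)
    if codon_a in stops or codon_b in stops:
        raise ValueError("stop codons are excluded from pairwise counting")
    pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not pos:
        return (0.0, 0.0)

    def walk(order: tuple[int, ...]) -> tuple[float, float, bool]:
        cur = codon_a
        sd = nd = 0.0
        clean = True
        for p in order:
            nxt = cur[:p] + codon_b[p] + cur[p + 1 :]
            if nxt in stops or cur in stops:
                # step through a stop: mark the path dirty but keep walking so
                # the all-blocked fallback still yields counts
                clean = False
                nd += 1.0
            elif forward[nxt] == forward[cur]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd, clean

    results = [walk(order) for order in permutations(pos)]
    clean = [(sd, nd) for sd, nd, ok in results if ok]
    use = clean if clean else [(sd, nd) for sd, nd, _ in results]
    sd = sum(x for x, _ in use) / len(use)
    nd = sum(y for _, y in use) / len(use)
    return sd, nd
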