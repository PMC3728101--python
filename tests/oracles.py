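"""Independent brute-force reference implementations used by the tests.

Everything here is written from first principles (direct enumeration over
pairs, columns, pathways, labellings or permutations) and deliberately
shares no code with the package internals it checks.
"""

from __future__ import annotations

import itertools
import math

GENETIC_CODE = {}
_BASES = "TCAG"
_AA = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
for _i, (_b1, _b2, _b3) in enumerate(itertools.product(_BASES, repeat=3)):
    GENETIC_CODE[_b1 + _b2 + _b3] = _AA[_i]


def clean_columns(seqs: list[str]) -> list[int]:
    """0-based columns where no sequence has a gap or N."""
    return [
        j
        for j in range(len(seqs[0]))
        if all(s[j] not in "-N" for s in seqs)
    ]


def pi_direct(seqs: list[str]) -> float:
    """Mean pairwise differences per clean site."""
    cols = clean_columns(seqs)
    if not cols:
        return math.nan
    total = 0
    n_pairs = 0
    for a, b in itertools.combinations(seqs, 2):
        total += sum(1 for j in cols if a[j] != b[j])
        n_pairs += 1
    return total / n_pairs / len(cols)


def seg_sites_direct(seqs: list[str]) -> int:
    cols = clean_columns(seqs)
    return sum(1 for j in cols if len({s[j] for s in seqs}) >= 2)


def mean_pairwise_k_direct(seqs: list[str]) -> float:
    cols = clean_columns(seqs)
    total = 0
    n_pairs = 0
    for a, b in itertools.combinations(seqs, 2):
        total += sum(1 for j in cols if a[j] != b[j])
        n_pairs += 1
    return total / n_pairs


def dxy_direct(group_a: list[str], group_b: list[str],
               start: int = 0, end: int | None = None) -> float:
    """Mean over cross pairs of (diffs / comparable sites) in [start, end)."""
    end = end if end is not None else len(group_a[0])
    vals = []
    for a in group_a:
        for b in group_b:
            comp = diff = 0
            for j in range(start, end):
                if a[j] in "-N" or b[j] in "-N":
                    continue
                comp += 1
                if a[j] != b[j]:
                    diff += 1
            if comp:
                vals.append(diff / comp)
    return sum(vals) / len(vals) if vals else math.nan


def ng_sites_direct(codon: str) -> float:
    """Synonymous site count of one codon by enumerating all 9 mutants."""
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if GENETIC_CODE[mut] != "*" and GENETIC_CODE[mut] == aa:
                s += 1 / 3
    return s


def ng_diffs_direct(ca: str, cb: str) -> tuple[float, float]:
    """Pathway-averaged (syn, nonsyn) difference counts between codons."""
    pos = [i for i in range(3) if ca[i] != cb[i]]
    if not pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(pos):
        cur = ca
        sd = nd = 0
        blocked = False
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1 :]
            if GENETIC_CODE[nxt] == "*" or GENETIC_CODE[cur] == "*":
                blocked = True
                nd += 1
            elif GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, blocked))
    ok = [(s, n) for s, n, b in paths if not b]
    use = ok if ok else [(s, n) for s, n, _ in paths]
    return (sum(s for s, _ in use) / len(use),
            sum(n for _, n in use) / len(use))


def tajima_d_direct(n: int, S: int, k: float) -> float:
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (k - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def fitch_exhaustive(children: dict, root, tip_states: dict) -> int:
    """Minimum substitutions over all ancestral labellings of a rooted tree
    for one column.  ``children`` maps internal node -> child list;
    ``tip_states`` maps tip -> set of allowed states."""
    internals = [n for n in children]
    best = math.inf
    states = "ACGT"

    def edge_cost(assign):
        cost = 0
        for parent, kids in children.items():
            for kid in kids:
                if kid in children:
                    cost += assign[parent] != assign[kid]
                else:
                    cost += min(assign[parent] != s for s in tip_states[kid])
        return cost

    for combo in itertools.product(states, repeat=len(internals)):
        assign = dict(zip(internals, combo))
        best = min(best, edge_cost(assign))
    return int(best)


def max_run_pvalue_exhaustive(match_rows: list[list[bool]],
                              observed_scores: list[float],
                              weights: list[float]) -> list[float]:
    """Exact permutation p-values for the weighted max-run statistic on a
    tiny projection: enumerate every column order."""
    n_cols = len(match_rows[0])
    maxima = []
    for perm in itertools.permutations(range(n_cols)):
        best = 0.0
        for row, w in zip(match_rows, weights):
            run = 0
            for c in perm:
                run = run + 1 if row[c] else 0
                best = max(best, run * w)
        maxima.append(best)
    out = []
    for obs in observed_scores:
        n_ge = sum(1 for m in maxima if m >= obs - 1e-9)
        out.append((1 + n_ge) / (len(maxima) + 1))
    return out
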