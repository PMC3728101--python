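"""Replicated validation experiments for the analysis pipeline.

These functions run the package end-to-end on simulated data with known
truth and summarise how it behaves: false-positive calibration of the
conversion scan, power to recover planted tracts, estimator calibration
(π against θ, Tajima's D under the neutral coalescent), and the chimera
scenario for the partition/donor-profile machinery.  They are used by the
test suite and the acceptance script; all randomness is controlled by a
single seed, with per-replicate streams derived deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parsimony import PartitionSpec, partition_incongruence, search_mp
from .popgen import pi_by_class, tajima_d
from .scan import scan_population
from .signatures import donor_profile
from .simulate import CHIMERA_TRACT, PlantedTract, SimConfig, simulate_dataset


def _sub_seed(seed: int, key: int, rep: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(key, rep))
               .generate_state(1)[0] % (2**31))


def scan_family_wise_rate(n_datasets: int = 500, n_perm: int = 999,
                          alpha: float = 0.05, seed: int = 0) -> float:
    """Fraction of no-conversion datasets with any significant fragment.

    Each dataset is a single population (two paralogs, six haplotypes each)
    simulated without conversion; under the permutation null this family-
    wise rate should be close to ``alpha``.
    """
    false_positive = 0
    for rep in range(n_datasets):
        cfg = SimConfig(seed=_sub_seed(seed, 1, rep), n_populations=1,
                        conv_rate=0.0)
        res = simulate_dataset(cfg)
        frags, _ = scan_population(res.alignment, "pop1", n_perm=n_perm,
                                   seed=_sub_seed(seed, 2, rep), alpha=alpha)
        if any(f.sim_p < alpha for f in frags):
            false_positive += 1
    return false_positive / n_datasets


def tract_recovery_rate(n_replicates: int = 100, n_perm: int = 999,
                        alpha: float = 0.05, seed: int = 0,
                        tract: tuple[int, int] = (451, 750)) -> float:
    """Fraction of replicates in which a planted 300 bp inter-paralog tract
    is recovered by a significant overlapping inter-paralog fragment.

    The tract segregates in half of the recipient group (three of six
    haplotypes), the situation the scan is designed to detect.
    """
    start, end = tract
    planted = (PlantedTract("pop1", "p1", "p2", start, end,
                            n_recipient_haplotypes=3),)
    recovered = 0
    for rep in range(n_replicates):
        cfg = SimConfig(seed=_sub_seed(seed, 3, rep), n_populations=1,
                        conv_rate=0.0)
        res = simulate_dataset(cfg, planted)
        frags, _ = scan_population(res.alignment, "pop1", n_perm=n_perm,
                                   seed=_sub_seed(seed, 4, rep), alpha=alpha)
        if any(f.sim_p < alpha and f.category == "inter_paralog"
               and f.start <= end and f.end >= start for f in frags):
            recovered += 1
    return recovered / n_replicates


def pi_recovers_theta(n_replicates: int = 100, theta: float = 0.01,
                      seed: int = 0) -> dict:
    """π estimated on simulated tips versus the generating θ.

    Returns the mean π across replicates, its standard error and the
    z-score of the deviation from θ.
    """
    values = []
    for rep in range(n_replicates):
        cfg = SimConfig(seed=_sub_seed(seed, 5, rep), n_populations=1,
                        conv_rate=0.0, theta_within=theta)
        res = simulate_dataset(cfg)
        s = pi_by_class(res.alignment, None, ("pop1", "p1"))
        values.append(s.pi_silent)
    mean = float(np.mean(values))
    se = float(np.std(values, ddof=1) / np.sqrt(len(values)))
    return {"mean_pi": mean, "se": se, "theta": theta,
            "z": (mean - theta) / se}


def neutral_tajima_mean(n_reps: int = 2000, n: int = 10, theta: float = 5.0,
                        seed: int = 0) -> float:
    """Mean Tajima's D over neutral coalescent simulations (msprime).

    Under the standard neutral model D has expectation near zero; this
    feeds segregating sites and mean pairwise differences from an
    independent coalescent simulator through the package's D computation.
    """
    import msprime  # optional test-time dependency

    total = 0.0
    used = 0
    rng_seed = _sub_seed(seed, 6, 0) or 1
    reps = msprime.sim_ancestry(
        samples=n, ploidy=1, sequence_length=1.0,
        num_replicates=n_reps, random_seed=rng_seed)
    mut_rng = np.random.default_rng(_sub_seed(seed, 7, 0))
    for ts in reps:
        mts = msprime.sim_mutations(
            ts, rate=theta / 2.0, random_seed=int(mut_rng.integers(1, 2**31)),
            discrete_genome=False)
        S = mts.num_sites
        if S == 0:
            continue
        k = mts.diversity(span_normalise=False)  # mean pairwise differences
        d = tajima_d(n, S, float(k))
        if np.isfinite(d):
            total += d
            used += 1
    return total / used


@dataclass
class ChimeraEvaluation:
    """Outcome of the chimera scenario: clade placements per partition and
    the donor-profile breakpoint error in bp."""

    placements: dict[str, tuple[str, str]]
    all_switch_clades: bool
    breakpoint_error_bp: float | None
    window: int


def evaluate_chimera(seed: int = 0, window: int = 60, step: int = 12,
                     n_starts: int = 3) -> ChimeraEvaluation:
    """Run the full chimera analysis: simulate a two-population dataset with
    a paralog-1-derived 3′ block in half of population 1's paralog-2
    haplotypes, build parsimony trees for the 5′ and 3′ partitions, and
    profile the converted class against its own orthologs and the donor."""
    junction = CHIMERA_TRACT[0]
    planted = (PlantedTract("pop1", "p1", "p2", *CHIMERA_TRACT,
                            n_recipient_haplotypes=3),)
    cfg = SimConfig(seed=_sub_seed(seed, 8, 0), n_populations=2,
                    conv_rate=0.0, include_outgroup=True)
    res = simulate_dataset(cfg, planted)
    aln = res.alignment
    chimeras = list(res.truth[-1].recipient_haplotypes)

    part_a = PartitionSpec("five_prime", 1, junction - 1)
    part_b = PartitionSpec("three_prime", junction, aln.length)
    trees_a, _ = search_mp(aln, part_a, n_starts=n_starts,
                           seed=_sub_seed(seed, 9, 0))
    trees_b, _ = search_mp(aln, part_b, n_starts=n_starts,
                           seed=_sub_seed(seed, 10, 0))
    clade_donor = [r.haplotype_id for r in aln.records if r.paralog == "p1"]
    clade_own = [r.haplotype_id for r in aln.records
                 if r.paralog == "p2" and r.haplotype_id not in chimeras]
    report = partition_incongruence(trees_a[0], trees_b[0], chimeras,
                                    clade_donor, clade_own)
    # clade A = donor paralog (p1), clade B = the chimeras' own paralog (p2):
    # a chimera should sit with its own paralog 5' of the junction and with
    # the donor 3' of it
    switches = all(v == ("B", "A") for v in report.assignments.values())

    own_refs = [r.haplotype_id for r in aln.records
                if r.paralog == "p2" and r.population == "pop2"]
    donor_refs = [r.haplotype_id for r in aln.records
                  if r.paralog == "p1" and r.population == "pop1"]
    prof = donor_profile(aln, chimeras, own_refs, donor_refs, window, step)
    error = (min(abs(b - junction) for b in prof.breakpoints)
             if prof.breakpoints else None)
    return ChimeraEvaluation(report.assignments, switches, error, window)
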