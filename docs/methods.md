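# Methods

This note documents the statistical models and procedures implemented in
`concerted`, the defaults they use, the design choices that were genuinely
open, and what the simulation-based tests do and do not establish.

## Data model

A `GroupedAlignment` holds aligned, phased haplotypes tagged with
(population, paralog) labels over the alphabet `{A,C,G,T,-,N}`.
Coordinates are 1-based with inclusive intervals throughout; conversions to
0-based indexing happen only inside functions at array boundaries. `-` is
an alignment gap, `N` missing data; both are excluded from counts and never
scored as differences. Within-group statistics use **listwise** exclusion
(a column with any gap/N in the group is dropped), matching the behaviour
of the classic polymorphism software whose tables these reproduce;
between-group window profiles use pairwise-complete exclusion so that a
single gapped sequence does not blank a window. The model assumes phased
haplotypes as deposited; phasing of heterozygous base calls is upstream of
this package.

Consensus sequences use majority rule with lexicographic tie-breaking
(codon-wise for translation, column-wise for divergence masking) — an
arbitrary but platform-independent rule; ties are rare in real data and the
choice only matters for determinism.

## Divergence (k_s, k_a)

`nei_gojobori_pair` implements the Nei–Gojobori (1986) proportion method:
per codon, the synonymous site count is the fraction of the nine possible
single-base changes that preserve the amino acid (changes to stop codons
count as nonsynonymous), averaged over the two sequences; multi-difference
codons are averaged over all minimal substitution pathways with equal
weight, with pathways through stop codons excluded (all pathways are used
if every one is blocked). Codons containing gaps, N, or a stop in either
sequence are excluded pairwise. Distances are Jukes–Cantor corrected,
`d = −(3/4)·ln(1 − 4p/3)`; `p ≥ 3/4` raises a saturation error rather than
returning a number. `k_a/k_s` is reported as undefined when `k_s = 0`
(printed `-`).

The method choice is fixed to Nei–Gojobori + JC because it is the default
of the standard desktop software for such tables and is fully specifiable;
maximum-likelihood codon models are out of scope.

`divergence_between_groups` offers two modes. `fixed_only` (default, the
convention behind "fixed divergence" tables) compares group consensus
sequences with every site that is polymorphic inside either group masked to
equality — polymorphic positions contribute sites but no differences.
`mean_pairwise` averages the four Nei–Gojobori counts over all
between-group pairs before forming proportions. Whether published tables
of this kind used consensus or single representative haplotypes is usually
unstated; `fixed_only` on consensus is the default here, with the pairwise
mode available for sensitivity checks.

## Polymorphism (π, S, Tajima's D)

π is Nei's nucleotide diversity: the mean over haplotype pairs of
differences per comparable site, with **no** n/(n−1) rescaling, again
matching the software convention for such tables. It is partitioned by
Nei–Gojobori site counting into synonymous and nonsynonymous classes;
"silent" pools synonymous and noncoding sites. Segregating coding sites
are classified by placing each variant base into the group's majority
codon background and comparing translations (a site is synonymous iff all
variants translate identically); sites with no clean background codon are
counted in totals but not classified.

Tajima's D uses the standard constants
(a₁,a₂,b₁,b₂,c₁,c₂,e₁,e₂) and is computed over all included sites. It is
**undefined** — returned as NaN, printed NA — when S = 0 or n < 4, never
silently zero.

## Sliding-window D_xy

Per window, D_xy is the mean over between-group pairs of
(differences / comparable sites); pairs with no comparable sites are
dropped from the mean and an empty window is NaN, not 0. Windows are
emitted while `start + window − 1 ≤ L` (no ragged final window), so the
profile matches the x-range convention of published plots. Windows with
fewer than 10 comparable sites (configurable) carry a low-confidence flag.
Defaults of 60 bp windows with 12 bp steps follow the plotting convention
for the target data type. A single window covering the alignment equals
the global D_xy by construction.

## Conversion scan

The scan is a Sawyer-statistic permutation test with population × paralog
group structure:

1. **Projection.** Each population's sequences are condensed to columns
   polymorphic within that population; columns containing any gap or N in
   scope are dropped (a column is droppable, never a match). Fewer than
   two polymorphic columns skips the scan with a warning.
2. **Fragments.** For every within-population pair, fragments are maximal
   runs of consecutive polymorphic sites at which the pair is identical
   (mismatch penalty `g = 0`, the default: fragments cannot span
   mismatches; with `g > 0` they become maximal-scoring segments, each
   mismatch costing `g` match units, extracted with the Ruzzo–Tompa
   algorithm). Fragments with fewer than two supporting sites are
   discarded; coordinates span the first to last supporting site in
   original alignment coordinates.
3. **Scores.** The default score weights each matching site by
   `−ln q̂`, where `q̂ = (matches + 1)/(sites + 2)` is the pair's smoothed
   match fraction across the projection. This makes scores comparable
   across pairs of very different similarity: in duplicated-gene data,
   intra-paralog pairs agree at ~95 % of polymorphic sites and produce
   long identity runs under the null, while inter-paralog pairs agree at
   ~50 %; an unweighted count maximum is therefore always dominated by
   dense pairs, and a genuinely converted inter-paralog run can never win.
   The pair-adaptive weighting — the same idea as the "BLAST-like"
   fragment scores of the original gene-conversion software — restores
   power without changing the null calibration, because each pair's match
   fraction is invariant under column permutation. A plain
   `score="count"` (run length) is available for the textbook statistic.
4. **Permutation p-values.** For each of `n_perm` permutations the
   polymorphic columns are shuffled as units and the maximum fragment
   score over all allowed pairs recorded; a fragment's global
   `sim_p = (1 + #{perm max ≥ score}) / (n_perm + 1)`, the conservative
   add-one estimator, with ties counted against significance. Using the
   across-pair maximum controls the family-wise error over pairs without a
   separate correction. With a fixed seed the p-values are
   bit-reproducible.
5. **Events.** Significant fragments (`sim_p < α`, default 0.05) are
   grouped by (population, inter-/intra-paralog); overlap-connected
   intervals are merged, and the cluster count is reported as the minimum
   number of conversion events.

Numeric parity with any particular external scanner is not promised; the
agreed summary is the count of significant non-overlapping events. The
scan cannot, by construction, detect conversions that are fixed in both
the donor and recipient groups of a population (such tracts leave no
polymorphism in scope); detecting segregating conversions — the situation
of interest for recent events — is its design target and what the
recovery experiments measure.

## Signatures

* **Shared-paralog sites**: a column where both paralogs of one population
  share a state that occurs in *no* sequence of any other population —
  operationalised as strict absence from every other population, the most
  conservative reading; the definition is symmetric across populations and
  paralog labels.
* **Haplotype classes**: single-linkage clustering (scipy) of a group's
  haplotypes on pairwise difference counts within a region, cut at a
  user-set maximum difference. Class delimitation thresholds for real
  data are a judgment call, so the cutoff is an explicit parameter rather
  than a guess; single-member classes are allowed and flagged.
* **Donor profiles**: windowed D_xy of a focal class against (a) its own
  paralog's orthologs and (b) the other paralog, with
  `delta = D_own − D_other`. Windows with `delta > threshold` (default
  0.05, i.e. the class is closer to the other paralog by more than 5 %
  divergence) are flagged as putatively converted. Breakpoints are placed
  at the midpoint between consecutive *confident* windows (|delta| above
  threshold) of opposite sign; windows straddling the junction have small
  |delta| and are skipped over, so breakpoint resolution is on the order
  of one window. The number of flagged windows is non-increasing in the
  threshold.

## Parsimony phylogenetics

Characters are bitmask-encoded (gap/N = any state, i.e. missing, not a
fifth state) and pattern-compressed; constant patterns are dropped. Fitch
scoring is exact; the heuristic search uses random-addition starting trees
followed by nearest-neighbour-interchange hill climbing, returning all
distinct best topologies found (equal-score NNI neighbours of the final
trees included). NNI rather than SPR/TBR is a deliberate simplification:
at the ~20–30-tip scale of within-species paralog data sets it finds the
same optima at a fraction of the cost. Taxa are processed in label-sorted
order so results are invariant to alignment record order.

The bootstrap resamples columns with replacement (multinomial weights over
patterns), runs a reduced search per replicate, and builds a 50 %
majority-rule consensus from bipartition frequencies, rooted on the
outgroup; supports are integer percentages. The default is 1000
replicates — supports at this problem size converge well before that — and
is configurable upward. Rooting never changes unrooted bipartitions.

`partition_incongruence` compares trees built from two gene regions: for
each focal (putative chimera) tip it walks rootward to the nearest
surrounding clade containing members of either defined reference clade and
reports the majority membership, plus the unrooted Robinson–Foulds
distance between the trees (dendropy).

## Simulator

The generator emulates the study system: a single duplication predating a
star-shaped split of (default) four populations, two paralogs evolving
jointly down each branch.

* Substitution: Jukes–Cantor-like (uniform sites, uniform replacement
  base), Poisson numbers per branch; keeps expectations closed-form and
  matches the JC correction used in analysis.
* Conversion: Poisson(`conv_rate`, default 1 per branch) events at uniform
  times; donor is paralog 1 with probability `donor_bias`; tract lengths
  geometric with mean `tract_mean` (default 100 bp — "tens to hundreds of
  bp", the field's working range; the true tract-length law in such
  systems is unknown and this is a modelling choice). A proposal is
  rejected if it overlaps a configured divergence island or if local
  donor–recipient divergence exceeds `meps_divergence_cutoff` (default
  0.3) — the minimal-efficient-processing-segment effect by which
  diverged sequence resists conversion.
* Tips: each (population, paralog) group draws haplotypes on a star
  genealogy with per-lineage mutation θ/2 per site, so E[π] = θ (default
  0.01, the order of silent diversity in the motivating populations). A
  coalescent within tips is a documented extension point; the star
  genealogy is adequate for calibrating estimators of π but produces
  negative Tajima's D, which is why neutrality checks of D use an external
  coalescent simulator (msprime) instead.
* Heights: `duplication_height` defaults to 0.05 expected
  substitutions/site (total paralog divergence ≈ 10 %, the overall
  nucleotide divergence scale of recently duplicated pairs whose k_s is a
  few-fold higher than the genome-wide average while k_a stays low — a
  neutral simulator cannot split the two, so it matches the overall
  scale); `split_height` 0.015 puts ortholog divergence at ~3 %.
* Recent, still-segregating conversions are planted explicitly
  (`PlantedTract`), either fixed in the recipient group or copied into the
  first k haplotypes (the chimeric-class scenario); indel/pseudogenisation
  is represented only as annotation, keeping all columns alignable.

All randomness flows from one mandatory seed through per-stage child
streams; regeneration is byte-identical. Bundled fixtures: a
single-population no-conversion null, a planted 300 bp tract, a
two-population chimera with outgroup (junction at column 924), and an
island scenario.

**What the simulations do not show**: real data have rate heterogeneity,
indels, selection on codons and within-population recombination, none of
which the generator produces; passing the calibration and recovery tests
demonstrates the scan's statistical behaviour under exchangeable-column
nulls and clean planted tracts, not robustness to alignment error or
selection.

## Validation experiments and problem sizes

`concerted.validation` runs the package end-to-end (the test suite and
`scripts/acceptance.py` call the same functions):

* scan calibration — 500 single-population no-conversion datasets,
  999 permutations each: family-wise significant-fragment rate at
  α = 0.05 (observed ≈ 0.03–0.04; the add-one estimator with tie counting
  is slightly conservative, as intended);
* power — 100 replicates with a planted segregating 300 bp tract:
  recovery by an overlapping significant inter-paralog fragment;
* Tajima's D — 2000 neutral coalescent replicates (msprime, n = 10,
  θ = 5) through the package's D computation;
* π/θ — 100 simulator replicates at θ = 0.01;
* chimera — partition trees and donor-profile breakpoint on the
  two-population chimera scenario.

These sizes were chosen to keep each experiment's Monte-Carlo error well
inside the property being asserted (e.g. SE ≈ 0.008 on the calibration
rate) while the whole battery runs in about a minute on one CPU.

## Known limitations

* No outer-sequence ("unknown donor") fragment detection; donors must be
  in the alignment.
* The scan's fragment scores are not numerically comparable to any
  external program's; only event counts are.
* `fixed_only` divergence on consensus sequences can differ from
  single-haplotype tables when groups are highly polymorphic.
* Breakpoint calls are window-resolution; no HMM-style segmentation.
* The simulator's star population tree and star within-population
  genealogies are deliberate simplifications.
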