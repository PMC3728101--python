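# concerted

Polymorphism, divergence and gene-conversion analysis for duplicated genes.

Tandem gene duplicates often exchange sequence by **gene conversion** — a
nonreciprocal copy-paste between paralogous loci. Repeated conversion
homogenises the copies (concerted evolution); islands of divergence that
resist it point to regions under selection; and rare directional events can
build **chimeric haplotypes** whose 5′ and 3′ halves descend from different
paralogs. `concerted` is a toolkit for dissecting these patterns in
population samples of duplicated genes, built for data sets of the shape
produced by population-level resequencing of paralog pairs: aligned,
phased haplotypes labelled by population and paralog (for example the
duplicated cytosolic aspartate-transaminase *GOT1* genes of the copepod
*Tigriopus californicus*, sequenced in four Californian populations).

## What it computes

* **Divergence** — Nei–Gojobori (1986) synonymous/nonsynonymous site and
  difference counts with Jukes–Cantor correction:
  `k_s = −(3/4)·ln(1 − 4·p_s/3)`, likewise `k_a`, and the constraint ratio
  `k_a/k_s`; fixed-difference and mean-pairwise modes between any two
  haplotype groups.
* **Polymorphism** — nucleotide diversity π by site class (synonymous,
  nonsynonymous, silent = synonymous + noncoding), segregating sites S per
  class, and Tajima's D.
* **Sliding-window D_xy** — windowed mean pairwise divergence between
  groups (e.g. 60 bp windows, 12 bp steps), the track on which conversion
  tracts appear as valleys and divergence islands as peaks.
* **Conversion scan** — a Sawyer-style permutation test: alignments are
  condensed to polymorphic sites; maximal runs of identity between sequence
  pairs ("inner fragments") are scored pair-adaptively and assigned global
  p-values by permuting columns, with group structure restricting the
  search to within-population pairs and classifying fragments as inter- or
  intra-paralog; overlap-connected significant fragments are merged into
  the minimum number of conversion events.
* **Signatures** — shared-paralog sites (a state carried by both paralogs
  of one population and no other population), single-linkage haplotype
  classing, and donor profiles that localise conversion breakpoints from
  the sign change of `D_xy(own orthologs) − D_xy(other paralog)`.
* **Parsimony phylogenetics** — Fitch scoring, random-addition + NNI
  search, bootstrap with 50 % majority-rule consensus and outgroup rooting,
  and a partition-incongruence report that shows a chimera switching
  clades between gene regions.
* **Forward simulator** — duplicate-gene evolution down a population tree
  with Poisson conversion events, geometric tract lengths, donor bias,
  divergence-dependent rejection (the MEPS effect) and protected islands;
  every accepted event is recorded as ground truth, so every stage above
  is testable without real data.

## A worked example

Plant a single 300 bp inter-paralog tract in half of the recipient group
and scan for it (`examples/03_conversion_scan.py`):

```python
from concerted import (PlantedTract, SimConfig, minimum_event_counts,
                       scan_population, simulate_dataset)

planted = (PlantedTract("pop1", donor_paralog="p1", recipient_paralog="p2",
                        start=451, end=750, n_recipient_haplotypes=3),)
res = simulate_dataset(SimConfig(seed=21, n_populations=1, conv_rate=0.0),
                       planted)
fragments, clusters = scan_population(res.alignment, "pop1", n_perm=999, seed=0)
```

Output (abridged):

```
842 fragments scored, 33 significant at 0.05:
  inter_paralog  pop1_p1_h2 vs pop1_p2_h1: columns 487..751 (42 sites, score 30.71, p=0.0010)
  inter_paralog  pop1_p1_h3 vs pop1_p2_h3: columns 443..690 (38 sites, score 29.08, p=0.0010)
  ...
minimum event counts: {('pop1', 'inter_paralog'): 1}
```

Every significant fragment is an inter-paralog pair run overlapping the
planted tract (451..750); the score is the run length at polymorphic sites
weighted by how unlikely a match is for that pair, and `p` is the global
permutation p-value. The overlapping fragments merge into a single
cluster: the scan reports exactly one conversion event, which is what was
simulated.

The other examples show the divergence/diversity tables
(`02_polymorphism_divergence.py`), conversion signatures and breakpoint
calling (`04_conversion_signatures.py`) and the partitioned-parsimony
fingerprint of a chimeric haplotype (`05_partition_phylogeny.py`).

## Command line

A thin CLI wraps the pipeline stages:

```bash
concerted simulate --out-dir data --seed 7 --plant pop1,p1,p2,451,750,3
concerted all --fasta data/alignment.fasta --metadata data/metadata.tsv \
    --coding-map data/coding_map.tsv --out-dir results --seed 7 \
    --partition first:1:923 --partition second:924:1224
```

`all` writes divergence/polymorphism tables, window profiles, fragment and
cluster reports, signature tables, Newick trees and a JSON manifest that
suffices to re-run the pipeline exactly.

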