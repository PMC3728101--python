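"""End-to-end orchestration: run every analysis stage on a dataset
directory and write plot-ready TSV/Newick outputs plus a JSON manifest.

Stage order follows the natural analysis flow: divergence and polymorphism
statistics → conversion scan → conversion signatures → partitioned
phylogenies.  Each stage is also runnable on its own through the functions
here or the thin CLI in :mod:`concerted.cli`.  Any stage failure aborts the
run with a stage-named error; outputs written so far are retained and the
manifest records the failed stage.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import (
    CodingMap,
    GroupedAlignment,
    load_alignment,
    load_coding_map,
)
from .parsimony import PartitionSpec, bootstrap_consensus
from .popgen import divergence_between_groups, pi_by_class, sliding_dxy
from .scan import classify_and_cluster, minimum_event_counts, scan_all_populations
from .signatures import class_haplotypes, donor_profile, shared_paralog_sites

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything needed to reproduce a full run."""

    fasta: str
    metadata: str
    out_dir: str
    seed: int
    coding_map: str | None = None
    window: int = 60
    step: int = 12
    n_perm: int = 10000
    alpha: float = 0.05
    g: float = 0.0
    score: str = "weighted"
    class_cutoff: int = 3
    partitions: list[tuple[str, int, int]] = field(default_factory=list)
    outgroup: str | None = None
    bootstrap_reps: int = 1000
    search_starts: int = 10

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw["partitions"] = [tuple(p) for p in raw.get("partitions", [])]
        return cls(**raw)


def _fmt(x: float, nd: int) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{x:.{nd}f}"


# -- stages ----------------------------------------------------------------


def stage_stats(aln: GroupedAlignment, cmap: CodingMap | None, out: Path,
                window: int, step: int) -> list[str]:
    """Divergence table, polymorphism table and window profiles."""
    written = []
    if cmap is not None:
        rows = []
        pops = aln.populations()
        for pop in pops:
            paralogs = [g[1] for g in aln.groups() if g[0] == pop]
            for a_idx in range(len(paralogs)):
                for b_idx in range(a_idx + 1, len(paralogs)):
                    ga, gb = (pop, paralogs[a_idx]), (pop, paralogs[b_idx])
                    pdv = divergence_between_groups(aln, cmap, ga, gb)
                    rows.append(
                        {
                            "comparison": f"{pop} {paralogs[a_idx]}/{paralogs[b_idx]}",
                            "type": "between_paralogs",
                            "ks": _fmt(pdv.ks, 3),
                            "ka": _fmt(pdv.ka, 3),
                            "ka_ks": _fmt(pdv.ratio, 3) if pdv.ratio is not None else "-",
                        }
                    )
        # ortholog comparisons against the first population
        ref = pops[0]
        for pop in pops[1:]:
            for par in [g[1] for g in aln.groups() if g[0] == ref]:
                if (pop, par) not in aln.groups():
                    continue
                pdv = divergence_between_groups(aln, cmap, (ref, par), (pop, par))
                rows.append(
                    {
                        "comparison": f"{ref} {par}/{pop} {par}",
                        "type": "orthologs",
                        "ks": _fmt(pdv.ks, 3),
                        "ka": _fmt(pdv.ka, 3),
                        "ka_ks": _fmt(pdv.ratio, 3) if pdv.ratio is not None else "-",
                    }
                )
        pd.DataFrame(rows).to_csv(out / "divergence.tsv", sep="\t", index=False)
        written.append("divergence.tsv")

    rows = []
    for pop, par in aln.groups():
        if len(aln.group_indices(pop, par)) < 2:
            logger.warning("group (%s, %s) has < 2 haplotypes; skipped", pop, par)
            continue
        s = pi_by_class(aln, cmap, (pop, par))
        rows.append(
            {
                "population": pop,
                "paralog": par,
                "n_hap": s.n_hap,
                "pi_syn": _fmt(s.pi_syn, 5),
                "s_syn": s.s_syn,
                "pi_nonsyn": _fmt(s.pi_nonsyn, 5),
                "s_nonsyn": s.s_nonsyn,
                "pi_silent": _fmt(s.pi_silent, 5),
                "s_silent": s.s_silent,
                "tajima_d": _fmt(s.tajima_d, 3),
            }
        )
    pd.DataFrame(rows).to_csv(out / "polymorphism.tsv", sep="\t", index=False)
    written.append("polymorphism.tsv")

    for pop in aln.populations():
        paralogs = [g[1] for g in aln.groups() if g[0] == pop]
        if len(paralogs) < 2:
            continue
        prof = sliding_dxy(aln, (pop, paralogs[0]), (pop, paralogs[1]),
                           window, step)
        name = f"dxy_{pop}_{paralogs[0]}_{paralogs[1]}.tsv"
        prof.to_frame().to_csv(out / name, sep="\t", index=False,
                               float_format="%.5f")
        written.append(name)
    return written


def stage_scan(aln: GroupedAlignment, out: Path, n_perm: int, alpha: float,
               g: float, score: str, seed: int) -> list[str]:
    fragments, clusters = scan_all_populations(
        aln, n_perm=n_perm, seed=seed, alpha=alpha, g=g, score=score
    )
    frows = [
        {
            "population": f.population,
            "category": f.category,
            "seq_i": f.seq_i,
            "seq_j": f.seq_j,
            "start": f.start,
            "end": f.end,
            "n_poly_sites": f.n_poly_sites,
            "score": f"{f.score:.5f}",
            "sim_p": f"{f.sim_p:.5f}" if f.sim_p is not None else "NA",
            "significant": bool(f.sim_p is not None and f.sim_p < alpha),
        }
        for f in fragments
    ]
    pd.DataFrame(frows).to_csv(out / "fragments.tsv", sep="\t", index=False)
    crows = [
        {
            "population": c.population,
            "category": c.category,
            "merged_start": c.start,
            "merged_end": c.end,
            "n_fragments": len(c.fragments),
        }
        for c in clusters
    ]
    pd.DataFrame(crows).to_csv(out / "clusters.tsv", sep="\t", index=False)
    counts = minimum_event_counts(clusters)
    with open(out / "event_counts.tsv", "w") as fh:
        fh.write("population\tcategory\tmin_events\n")
        for (pop, cat), n in sorted(counts.items()):
            fh.write(f"{pop}\t{cat}\t{n}\n")
    return ["fragments.tsv", "clusters.tsv", "event_counts.tsv"]


def stage_signatures(aln: GroupedAlignment, out: Path, window: int, step: int,
                     class_cutoff: int) -> list[str]:
    written = []
    if len(aln.populations()) >= 2:
        calls = shared_paralog_sites(aln)
        pd.DataFrame(
            [
                {
                    "column": c.column,
                    "population": c.population,
                    "state": c.shared_state,
                    "status_a": c.status_in_paralog_a,
                    "status_b": c.status_in_paralog_b,
                }
                for c in calls
            ]
        ).to_csv(out / "shared_sites.tsv", sep="\t", index=False)
        written.append("shared_sites.tsv")
    else:
        logger.warning("single population: shared-paralog sites undefined")

    rows = []
    profiles = []
    for pop, par in aln.groups():
        classes = class_haplotypes(aln, (pop, par), (1, aln.length), class_cutoff)
        for hc in classes:
            rows.append(
                {
                    "population": pop,
                    "paralog": par,
                    "class": hc.label,
                    "members": ",".join(hc.members),
                    "singleton": hc.singleton,
                }
            )
        if len(classes) < 2 or len(aln.populations()) < 2:
            continue
        other_paralogs = [g[1] for g in aln.groups() if g[0] == pop and g[1] != par]
        own_refs = [
            r.haplotype_id for r in aln.records
            if r.paralog == par and r.population != pop
        ]
        for hc in classes:
            for other_par in other_paralogs:
                other_refs = [
                    r.haplotype_id for r in aln.records
                    if r.population == pop and r.paralog == other_par
                ]
                if not own_refs or not other_refs:
                    continue
                prof = donor_profile(aln, hc.members, own_refs, other_refs,
                                     window, step, label=f"{pop}_{par}_{hc.label}")
                profiles.append((f"donor_profile_{pop}_{par}_{hc.label}_{other_par}",
                                 prof))
    pd.DataFrame(rows).to_csv(out / "haplotype_classes.tsv", sep="\t", index=False)
    written.append("haplotype_classes.tsv")
    for name, prof in profiles:
        prof.to_frame().to_csv(out / f"{name}.tsv", sep="\t", index=False,
                               float_format="%.5f")
        written.append(f"{name}.tsv")
    return written


def stage_phylo(aln: GroupedAlignment, out: Path,
                partitions: list[tuple[str, int, int]], outgroup: str | None,
                n_reps: int, n_starts: int, seed: int) -> list[str]:
    written = []
    specs = [PartitionSpec(*p) for p in partitions] or [
        PartitionSpec("full", 1, aln.length)
    ]
    for k, spec in enumerate(specs):
        sub_seed = int(np.random.SeedSequence(seed, spawn_key=(100 + k,))
                       .generate_state(1)[0] % (2**31))
        tree = bootstrap_consensus(aln, spec, n_reps=n_reps, seed=sub_seed,
                                   outgroup=outgroup)
        name = f"tree_{spec.name}.nwk"
        with open(out / name, "w") as fh:
            fh.write(tree.as_string(schema="newick", suppress_rooting=True))
        written.append(name)
    return written


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "concerted",
        "version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "stages": {},
        "status": "RUNNING",
    }

    def run_stage(name: str, fn, *args, **kwargs):
        t0 = time.time()
        logger.info("stage %s ...", name)
        try:
            files = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 — manifest must record the stage
            manifest["stages"][name] = {"status": "FAILED", "error": str(exc)}
            manifest["status"] = "FAILED"
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2)
            raise StageError(name, exc) from exc
        manifest["stages"][name] = {
            "status": "OK",
            "seconds": round(time.time() - t0, 3),
            "outputs": files,
        }
        return files

    def load():
        aln = load_alignment(config.fasta, config.metadata)
        cmap = load_coding_map(config.coding_map) if config.coding_map else None
        return aln, cmap

    try:
        aln, cmap = load()
        manifest["stages"]["seq_model"] = {
            "status": "OK",
            "n_records": len(aln),
            "length": aln.length,
        }
    except Exception as exc:  # noqa: BLE001
        manifest["stages"]["seq_model"] = {"status": "FAILED", "error": str(exc)}
        manifest["status"] = "FAILED"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise StageError("seq_model", exc) from exc

    run_stage("stats", stage_stats, aln, cmap, out, config.window, config.step)
    run_stage("scan", stage_scan, aln, out, config.n_perm, config.alpha,
              config.g, config.score, config.seed)
    run_stage("signatures", stage_signatures, aln, out, config.window,
              config.step, config.class_cutoff)
    run_stage("phylo", stage_phylo, aln, out, config.partitions,
              config.outgroup, config.bootstrap_reps, config.search_starts,
              config.seed)

    manifest["status"] = "OK"
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
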