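"""Sequence-level footprints of gene conversion.

Three complementary signatures:

* **shared-paralog sites** — alignment columns where both paralogs of one
  population share a state that occurs in no sequence of any other
  population; repeated within-population conversion leaves such sites
  scattered along the gene;
* **haplotype classing** — single-linkage clustering of a group's
  haplotypes over a region, used to separate e.g. "donor-like" from
  "recipient-like" allele classes of a converted paralog;
* **donor profiling** — windowed divergence of a focal haplotype class
  against its own orthologs versus the other paralog.  A chimeric class
  created by directional conversion is *closer to the other paralog* in the
  converted region and closer to its own orthologs elsewhere, so the
  difference track changes sign at the conversion breakpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .alignment import GAP, AlignmentError, GroupedAlignment
from .popgen import WindowProfile, _resolve_rows, sliding_dxy


@dataclass(frozen=True)
class SharedSiteCall:
    """A column where both paralogs of one population share a state absent
    from every other population."""

    column: int  # 1-based
    population: str
    shared_state: str
    status_in_paralog_a: str  # "fixed" | "polymorphic"
    status_in_paralog_b: str


def shared_paralog_sites(aln: GroupedAlignment) -> list[SharedSiteCall]:
    """All shared-paralog site calls, evaluated per population.

    A state qualifies when it occurs in both paralog groups of the focal
    population and in no sequence (either paralog) of any other population.
    Gap and N are never states.  Requires ≥ 2 populations.
    """
    pops = aln.populations()
    if len(pops) < 2:
        raise AlignmentError(
            "shared-paralog sites are undefined for a single-population alignment"
        )
    m = aln.matrix
    calls: list[SharedSiteCall] = []
    for pop in pops:
        paralogs = []
        for r in aln.records:
            if r.population == pop and r.paralog not in paralogs:
                paralogs.append(r.paralog)
        if len(paralogs) < 2:
            continue
        other_rows = [i for i, r in enumerate(aln.records) if r.population != pop]
        other = m[other_rows]
        for pa_idx in range(len(paralogs)):
            for pb_idx in range(pa_idx + 1, len(paralogs)):
                rows_a = aln.group_indices(pop, paralogs[pa_idx])
                rows_b = aln.group_indices(pop, paralogs[pb_idx])
                sub_a, sub_b = m[rows_a], m[rows_b]
                for j in range(aln.length):
                    col_a = sub_a[:, j][sub_a[:, j] < GAP]
                    col_b = sub_b[:, j][sub_b[:, j] < GAP]
                    if col_a.size == 0 or col_b.size == 0:
                        continue
                    states_a = set(col_a.tolist())
                    states_b = set(col_b.tolist())
                    shared = states_a & states_b
                    if not shared:
                        continue
                    col_other = other[:, j][other[:, j] < GAP]
                    elsewhere = set(col_other.tolist())
                    for s in sorted(shared):
                        if s in elsewhere:
                            continue
                        from .alignment import ALPHABET

                        calls.append(
                            SharedSiteCall(
                                column=j + 1,
                                population=pop,
                                shared_state=ALPHABET[s],
                                status_in_paralog_a=(
                                    "fixed" if states_a == {s} else "polymorphic"
                                ),
                                status_in_paralog_b=(
                                    "fixed" if states_b == {s} else "polymorphic"
                                ),
                            )
                        )
    return calls


# -- haplotype classes -----------------------------------------------------


@dataclass
class HaplotypeClass:
    """A cluster of haplotypes; labelled by its smallest member id."""

    label: str
    members: list[str]

    @property
    def singleton(self) -> bool:
        return len(self.members) == 1


def pairwise_differences(aln: GroupedAlignment, rows: np.ndarray,
                         start: int, end: int) -> np.ndarray:
    """Pairwise difference-count matrix over columns start..end (1-based),
    counting only sites where both sequences are unambiguous."""
    m = aln.matrix[rows, start - 1 : end]
    n = len(rows)
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            ok = (m[a] < GAP) & (m[b] < GAP)
            d[a, b] = d[b, a] = float(((m[a] != m[b]) & ok).sum())
    return d


def class_haplotypes(aln: GroupedAlignment, group, region: tuple[int, int],
                     max_within_class_diff: int) -> list[HaplotypeClass]:
    """Single-linkage classes of a group's haplotypes within a region.

    Haplotypes are chained together whenever some pair differs by at most
    ``max_within_class_diff`` sites in the region; classes are labelled by
    their lexicographically smallest member id and returned in label order.
    Single-member classes are permitted (see :attr:`HaplotypeClass.singleton`).
    """
    rows = _resolve_rows(aln, group)
    ids = [aln.records[i].haplotype_id for i in rows]
    start, end = region
    if not (1 <= start <= end <= aln.length):
        raise AlignmentError(f"region {region} outside alignment")
    if len(rows) == 1:
        return [HaplotypeClass(ids[0], ids)]
    d = pairwise_differences(aln, rows, start, end)
    z = linkage(squareform(d, checks=False), method="single")
    assignment = fcluster(z, t=max_within_class_diff, criterion="distance")
    classes: dict[int, list[str]] = {}
    for hid, c in zip(ids, assignment):
        classes.setdefault(int(c), []).append(hid)
    out = [HaplotypeClass(min(members), sorted(members))
           for members in classes.values()]
    out.sort(key=lambda hc: hc.label)
    return out


# -- donor profiling -------------------------------------------------------


@dataclass
class DonorProfile:
    """Windowed own-vs-other divergence contrast for one haplotype class.

    ``delta[w] = dxy_to_own[w] − dxy_to_other[w]``; windows with
    ``delta > call_threshold`` are flagged as putatively converted (the
    class is closer to the other paralog there).  Breakpoints are placed at
    the midpoint between adjacent windows where delta changes sign with
    |delta| above the threshold on both sides."""

    focal_label: str
    own: WindowProfile
    other: WindowProfile
    call_threshold: float
    delta: np.ndarray
    converted_windows: np.ndarray  # boolean per window
    breakpoints: list[float]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "start": self.own.starts,
                "end": self.own.ends,
                "mid": self.own.midpoints,
                "dxy_own": self.own.dxy,
                "dxy_other": self.other.dxy,
                "delta": self.delta,
                "converted": self.converted_windows,
            }
        )


def donor_profile(aln: GroupedAlignment, focal_class: Sequence[str],
                  own_ortholog_refs, other_paralog_refs,
                  window: int = 60, step: int = 12,
                  call_threshold: float = 0.05,
                  label: str | None = None) -> DonorProfile:
    """Contrast a focal haplotype class against two reference sets.

    ``own_ortholog_refs`` are sequences of the focal class's own paralog
    (typically orthologs from other populations); ``other_paralog_refs``
    are sequences of the other paralog (the candidate conversion donor).
    Both must be disjoint from the focal class.
    """
    focal_rows = set(_resolve_rows(aln, list(focal_class)).tolist())
    own_rows = _resolve_rows(aln, own_ortholog_refs)
    other_rows = _resolve_rows(aln, other_paralog_refs)
    if len(own_rows) == 0 or len(other_rows) == 0:
        raise AlignmentError("reference group is empty")
    for name, rows in (("own_ortholog_refs", own_rows),
                       ("other_paralog_refs", other_rows)):
        if focal_rows & set(rows.tolist()):
            raise AlignmentError(f"{name} overlaps the focal class")

    focal_ids = list(focal_class)
    own_ids = [aln.records[i].haplotype_id for i in own_rows]
    other_ids = [aln.records[i].haplotype_id for i in other_rows]
    own = sliding_dxy(aln, focal_ids, own_ids, window, step,
                      labels=("focal", "own_orthologs"))
    other = sliding_dxy(aln, focal_ids, other_ids, window, step,
                        labels=("focal", "other_paralog"))
    delta = own.dxy - other.dxy
    converted = np.asarray([bool(d > call_threshold) if np.isfinite(d) else False
                            for d in delta])
    # breakpoints: sign changes between consecutive *confident* windows
    # (|delta| > threshold); windows straddling the junction have small
    # |delta| and are skipped over
    breakpoints: list[float] = []
    confident = [w for w in range(len(delta))
                 if np.isfinite(delta[w]) and abs(delta[w]) > call_threshold]
    for prev, cur in zip(confident, confident[1:]):
        if delta[prev] * delta[cur] < 0:
            breakpoints.append(float((own.midpoints[prev] + own.midpoints[cur]) / 2.0))
    return DonorProfile(label or ",".join(focal_ids), own, other,
                        call_threshold, delta, converted, breakpoints)
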