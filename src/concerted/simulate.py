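"""Forward simulator of duplicate-gene evolution with gene conversion.

A single ancestral sequence is duplicated at ``duplication_height``
(expected substitutions/site above the tips); the two paralog lineages then
evolve jointly down a star population tree (populations split together at
``split_height``).  Substitutions follow a Jukes–Cantor-like model (uniform
sites, uniform replacement base).  Along every branch where the two
paralogs coexist, conversion events arrive as a Poisson process (expected
``conv_rate`` events per branch): each copies a geometric-length tract from
a donor paralog (chosen with probability ``donor_bias`` to be paralog 1)
onto the other, and is *rejected* when the tract overlaps a configured
divergence island or when local donor–recipient divergence exceeds the
``meps_divergence_cutoff`` (the minimal-efficient-processing-segment
effect: diverged sequence resists conversion).  Tip haplotypes are drawn on
a star genealogy with per-lineage mutation rate ``theta_within/2`` per
site, so expected within-group diversity π equals ``theta_within``.

Every accepted conversion is recorded as a :class:`TruthEvent`, giving
downstream detection code a ground truth to be scored against.  Recent,
still-segregating conversions (the chimeric-haplotype scenario) can be
planted explicitly with :class:`PlantedTract`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .alignment import ALPHABET, CodingMap, GroupedAlignment, Record


class ConfigError(ValueError):
    """Invalid simulation configuration (raised before any sampling)."""


@dataclass(frozen=True)
class SimConfig:
    """Scenario parameters; all heights/rates in expected substitutions per
    site, tract lengths in bp.  ``seed`` is mandatory."""

    seed: int
    n_populations: int = 4
    haplotypes_per_group: int = 6
    seq_length: int = 1224
    duplication_height: float = 0.05
    split_height: float = 0.015
    theta_within: float = 0.01
    conv_rate: float = 1.0
    tract_mean: float = 100.0
    donor_bias: float = 0.5
    meps_divergence_cutoff: float = 0.3
    island_intervals: tuple[tuple[int, int], ...] = ()
    include_outgroup: bool = False
    outgroup_height: float = 0.05

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.n_populations < 1 or self.haplotypes_per_group < 1:
            raise ConfigError("need ≥ 1 population and ≥ 1 haplotype per group")
        if self.seq_length < 3 or self.seq_length % 3:
            raise ConfigError("seq_length must be positive and divisible by 3")
        for name in ("duplication_height", "split_height", "theta_within",
                     "conv_rate", "tract_mean", "outgroup_height"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be ≥ 0")
        if self.split_height > self.duplication_height:
            raise ConfigError("populations cannot split before the duplication")
        if not 0.0 <= self.donor_bias <= 1.0:
            raise ConfigError("donor_bias must be in [0, 1]")
        for start, end in self.island_intervals:
            if not (1 <= start <= end <= self.seq_length):
                raise ConfigError(f"island {start}..{end} outside the sequence")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw["island_intervals"] = tuple(tuple(x) for x in raw.get("island_intervals", ()))
        return cls(**raw)


PARALOGS = ("p1", "p2")


@dataclass(frozen=True)
class TruthEvent:
    """An accepted conversion event: where, when, and in which direction."""

    branch: str  # "ancestral" or a population label
    time: float  # position along the branch (0 = branch start)
    donor_paralog: str
    recipient_paralog: str
    recipient_lineage: str
    start: int  # 1-based inclusive
    end: int
    recipient_haplotypes: tuple[str, ...] = ()  # empty = whole lineage


@dataclass(frozen=True)
class PlantedTract:
    """A deterministic conversion to apply at the tips.

    With ``n_recipient_haplotypes`` None the tract is fixed in the
    recipient group (copied before haplotype sampling); otherwise it is
    copied into the first k haplotypes only, leaving the conversion
    segregating — the chimeric-class scenario."""

    population: str
    donor_paralog: str
    recipient_paralog: str
    start: int
    end: int
    n_recipient_haplotypes: int | None = None


@dataclass
class SimResult:
    alignment: GroupedAlignment
    coding_map: CodingMap
    truth: list[TruthEvent]
    config: SimConfig


def _substitute(seq: np.ndarray, n: int, rng: np.random.Generator) -> None:
    if n <= 0:
        return
    pos = rng.integers(0, seq.size, size=n)
    shift = rng.integers(1, 4, size=n)
    for p, s in zip(pos, shift):
        seq[p] = (seq[p] + s) % 4


def _overlaps_island(start: int, end: int,
                     islands: Sequence[tuple[int, int]]) -> bool:
    return any(start <= ie and end >= is_ for is_, ie in islands)


def _evolve_branch(state: dict[str, np.ndarray], t_len: float, branch: str,
                   cfg: SimConfig, rng: np.random.Generator,
                   truth: list[TruthEvent]) -> None:
    """Evolve both paralogs along one branch, interleaving substitutions and
    conversion attempts in time order."""
    L = cfg.seq_length
    events: list[tuple[float, str]] = []
    n_sub = {p: rng.poisson(t_len * L) for p in PARALOGS}
    for p in PARALOGS:
        events.extend((rng.random(), f"sub:{p}") for _ in range(int(n_sub[p])))
    for _ in range(int(rng.poisson(cfg.conv_rate))):
        events.append((rng.random(), "conv"))
    events.sort(key=lambda ev: ev[0])
    for time, kind in events:
        if kind.startswith("sub:"):
            _substitute(state[kind[4:]], 1, rng)
            continue
        donor = "p1" if rng.random() < cfg.donor_bias else "p2"
        recipient = "p2" if donor == "p1" else "p1"
        start = int(rng.integers(1, L + 1))
        length = int(rng.geometric(1.0 / cfg.tract_mean)) if cfg.tract_mean > 0 else 1
        end = min(L, start + length - 1)
        if _overlaps_island(start, end, cfg.island_intervals):
            continue  # islands resist inter-paralog conversion
        seg = slice(start - 1, end)
        local_div = float(np.mean(state[donor][seg] != state[recipient][seg]))
        if local_div > cfg.meps_divergence_cutoff:
            continue  # MEPS: too diverged to convert
        state[recipient][seg] = state[donor][seg]
        truth.append(TruthEvent(branch, time * t_len if t_len > 0 else 0.0,
                                donor, recipient, branch, start, end))


def simulate_dataset(cfg: SimConfig,
                     planted: Sequence[PlantedTract] = ()) -> SimResult:
    """Run the simulation and return alignment, coding map and truth events.

    Bit-reproducible for a fixed config; all randomness flows from
    ``cfg.seed`` through per-stage child streams.
    """
    cfg.validate()
    for pt in planted:
        if not (1 <= pt.start <= pt.end <= cfg.seq_length):
            raise ConfigError(f"planted tract {pt.start}..{pt.end} outside sequence")
        if pt.donor_paralog == pt.recipient_paralog:
            raise ConfigError("planted tract must be inter-paralog")
    ss = np.random.SeedSequence(cfg.seed)
    rng_anc, rng_branch, rng_tips, rng_out = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    L = cfg.seq_length
    truth: list[TruthEvent] = []

    ancestor = rng_anc.integers(0, 4, size=L).astype(np.int8)
    outgroup_seq = None
    if cfg.include_outgroup:
        outgroup_seq = ancestor.copy()
        _substitute(outgroup_seq, int(rng_out.poisson(
            (cfg.outgroup_height + cfg.duplication_height) * L)), rng_out)

    # joint lineage from duplication down to the population split
    state = {"p1": ancestor.copy(), "p2": ancestor.copy()}
    _evolve_branch(state, cfg.duplication_height - cfg.split_height,
                   "ancestral", cfg, rng_branch, truth)

    pops = [f"pop{i + 1}" for i in range(cfg.n_populations)]
    pop_state: dict[str, dict[str, np.ndarray]] = {}
    for pop in pops:
        st = {p: state[p].copy() for p in PARALOGS}
        _evolve_branch(st, cfg.split_height, pop, cfg, rng_branch, truth)
        pop_state[pop] = st

    # fixed planted tracts (population level, before haplotype sampling)
    for pt in planted:
        if pt.n_recipient_haplotypes is None:
            st = pop_state[pt.population]
            seg = slice(pt.start - 1, pt.end)
            st[pt.recipient_paralog][seg] = st[pt.donor_paralog][seg]
            truth.append(TruthEvent(pt.population, 0.0, pt.donor_paralog,
                                    pt.recipient_paralog, pt.population,
                                    pt.start, pt.end))

    # tip haplotypes on a star genealogy
    records: list[Record] = []
    haps: dict[tuple[str, str], list[np.ndarray]] = {}
    for pop in pops:
        for par in PARALOGS:
            group = []
            for k in range(cfg.haplotypes_per_group):
                seq = pop_state[pop][par].copy()
                _substitute(seq, int(rng_tips.poisson(cfg.theta_within / 2.0 * L)),
                            rng_tips)
                group.append(seq)
            haps[(pop, par)] = group

    # segregating planted tracts (chimeric classes)
    for pt in planted:
        if pt.n_recipient_haplotypes is not None:
            donor_seq = pop_state[pt.population][pt.donor_paralog]
            seg = slice(pt.start - 1, pt.end)
            converted = []
            for k in range(pt.n_recipient_haplotypes):
                haps[(pt.population, pt.recipient_paralog)][k][seg] = donor_seq[seg]
                converted.append(f"{pt.population}_{pt.recipient_paralog}_h{k + 1}")
            truth.append(TruthEvent(pt.population, 0.0, pt.donor_paralog,
                                    pt.recipient_paralog, pt.population,
                                    pt.start, pt.end, tuple(converted)))

    for pop in pops:
        for par in PARALOGS:
            for k, seq in enumerate(haps[(pop, par)]):
                records.append(Record(f"{pop}_{par}_h{k + 1}", pop, par,
                                      "".join(ALPHABET[b] for b in seq)))
    if outgroup_seq is not None:
        records.append(Record("outgroup", "outgroup", "outgroup",
                              "".join(ALPHABET[b] for b in outgroup_seq)))

    cmap = CodingMap(((1, L),), 0, 1)
    return SimResult(GroupedAlignment(records), cmap, truth, cfg)


def write_truth_events(truth: Sequence[TruthEvent], path: str | Path) -> None:
    """Truth events as TSV (branch, time, donor, recipient, lineage, start,
    end, recipient_haplotypes)."""
    with open(path, "w") as fh:
        fh.write("branch\ttime\tdonor_paralog\trecipient_paralog\t"
                 "recipient_lineage\tstart\tend\trecipient_haplotypes\n")
        for ev in truth:
            fh.write(f"{ev.branch}\t{ev.time:.6f}\t{ev.donor_paralog}\t"
                     f"{ev.recipient_paralog}\t{ev.recipient_lineage}\t"
                     f"{ev.start}\t{ev.end}\t{','.join(ev.recipient_haplotypes)}\n")


# -- bundled worked fixtures -----------------------------------------------


@dataclass
class Fixture:
    name: str
    result: SimResult
    planted: tuple[PlantedTract, ...] = ()
    notes: str = ""


#: pinned seeds for the bundled fixtures (deterministic regeneration)
FIXTURE_SEEDS = {"null": 1301, "planted_tract": 1302, "chimera": 1303,
                 "islands": 1304}

#: the chimera fixture's conversion junction (tract runs to the 3' end)
CHIMERA_TRACT = (924, 1224)
PLANTED_TRACT = (451, 750)


def make_worked_fixtures() -> dict[str, Fixture]:
    """Deterministic toy datasets exercising every pipeline stage.

    ``null`` — one population, no conversion (scan calibration);
    ``planted_tract`` — a single 300 bp inter-paralog tract segregating in
    half of the recipient group;
    ``chimera`` — two populations plus an outgroup, with a paralog-1-derived
    3′ block (columns 924–1224) carried by half of population 1's paralog-2
    haplotypes;
    ``islands`` — frequent conversion everywhere except two divergence
    islands.
    """
    out: dict[str, Fixture] = {}

    cfg = SimConfig(seed=FIXTURE_SEEDS["null"], n_populations=1, conv_rate=0.0)
    out["null"] = Fixture("null", simulate_dataset(cfg),
                          notes="no-conversion null, one population")

    planted = (PlantedTract("pop1", "p1", "p2", *PLANTED_TRACT,
                            n_recipient_haplotypes=3),)
    cfg = SimConfig(seed=FIXTURE_SEEDS["planted_tract"], n_populations=1,
                    conv_rate=0.0)
    out["planted_tract"] = Fixture("planted_tract",
                                   simulate_dataset(cfg, planted), planted,
                                   notes="single 300 bp inter-paralog tract")

    planted = (PlantedTract("pop1", "p1", "p2", *CHIMERA_TRACT,
                            n_recipient_haplotypes=3),)
    cfg = SimConfig(seed=FIXTURE_SEEDS["chimera"], n_populations=2,
                    conv_rate=0.0, include_outgroup=True)
    out["chimera"] = Fixture("chimera", simulate_dataset(cfg, planted), planted,
                             notes="paralog-1-derived 3' block in half of "
                                   "pop1's paralog-2 haplotypes")

    cfg = SimConfig(seed=FIXTURE_SEEDS["islands"], n_populations=1,
                    conv_rate=6.0,
                    island_intervals=((301, 420), (801, 920)))
    out["islands"] = Fixture("islands", simulate_dataset(cfg),
                             notes="conversion suppressed inside two islands")
    return out
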