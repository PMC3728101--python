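"""Grouped haplotype alignments, coding annotation and per-site classification.

The central container is :class:`GroupedAlignment`: a gapped multiple-sequence
alignment of phased haplotypes, each tagged with a population and a paralog
label.  All downstream statistics (diversity, divergence, conversion scans,
parsimony) operate on this container.  Coordinates are 1-based and intervals
are inclusive throughout the package; conversion to 0-based indexing happens
only at array boundaries inside functions.

Residues are restricted to the alphabet ``{A, C, G, T, -, N}``.  ``-`` is an
alignment gap and ``N`` is missing data; both are excluded from polymorphism
and divergence counts (a site with missing data is never counted as a
difference).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: integer encoding of the residue alphabet
ALPHABET = "ACGT-N"
A, C, G, T, GAP, NMISS = range(6)
_CODE = {ch: i for i, ch in enumerate(ALPHABET)}


class AlignmentError(ValueError):
    """Raised for malformed alignments (length mismatches, empty input)."""


class MetadataError(ValueError):
    """Raised when sequence ids and the metadata table disagree."""


class UndefinedResultError(ValueError):
    """Raised when every position of a comparison is excluded."""


def encode(residues: str) -> np.ndarray:
    """Encode a residue string as an int8 vector (A=0,C=1,G=2,T=3,-=4,N=5).

    Characters outside the alphabet are mapped to N with a logged warning.
    """
    arr = np.empty(len(residues), dtype=np.int8)
    unknown = 0
    for i, ch in enumerate(residues.upper()):
        code = _CODE.get(ch)
        if code is None:
            code = NMISS
            unknown += 1
        arr[i] = code
    if unknown:
        logger.warning("%d unknown characters mapped to N", unknown)
    return arr


def decode(arr: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in arr)


@dataclass(frozen=True)
class Record:
    """One haplotype: id, population label, paralog label, residues."""

    haplotype_id: str
    population: str
    paralog: str
    residues: str

    def __post_init__(self):
        object.__setattr__(self, "residues", self.residues.upper())

    @property
    def group(self) -> tuple[str, str]:
        return (self.population, self.paralog)


class GroupedAlignment:
    """Aligned haplotypes tagged with (population, paralog) group labels.

    Invariants: all residue strings share one length, haplotype ids are
    unique, population and paralog labels are non-empty.
    """

    def __init__(self, records: Sequence[Record]):
        records = list(records)
        if not records:
            raise AlignmentError("alignment has no records")
        length = len(records[0].residues)
        seen: set[str] = set()
        for rec in records:
            if len(rec.residues) != length:
                raise AlignmentError(
                    f"record {rec.haplotype_id!r} has length {len(rec.residues)}, "
                    f"expected {length}"
                )
            if rec.haplotype_id in seen:
                raise AlignmentError(f"duplicate haplotype id {rec.haplotype_id!r}")
            if not rec.population or not rec.paralog:
                raise MetadataError(
                    f"record {rec.haplotype_id!r} lacks a population or paralog label"
                )
            seen.add(rec.haplotype_id)
        self.records: list[Record] = records
        self.length: int = length
        self._matrix = np.vstack([encode(r.residues) for r in records])

    # -- basic access -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    @property
    def matrix(self) -> np.ndarray:
        """(n_records, length) int8 matrix; see :data:`ALPHABET`."""
        return self._matrix

    @property
    def ids(self) -> list[str]:
        return [r.haplotype_id for r in self.records]

    def index_of(self, haplotype_id: str) -> int:
        for i, r in enumerate(self.records):
            if r.haplotype_id == haplotype_id:
                return i
        raise KeyError(haplotype_id)

    def groups(self) -> list[tuple[str, str]]:
        """Distinct (population, paralog) pairs in input order."""
        out: list[tuple[str, str]] = []
        for r in self.records:
            if r.group not in out:
                out.append(r.group)
        return out

    def populations(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.population not in out:
                out.append(r.population)
        return out

    def group_indices(self, population: str | None = None,
                      paralog: str | None = None) -> np.ndarray:
        """Row indices of records matching the given labels (None = any)."""
        idx = [
            i
            for i, r in enumerate(self.records)
            if (population is None or r.population == population)
            and (paralog is None or r.paralog == paralog)
        ]
        return np.asarray(idx, dtype=np.intp)

    def rows_for_ids(self, ids: Iterable[str]) -> np.ndarray:
        return np.asarray([self.index_of(i) for i in ids], dtype=np.intp)

    def subset(self, rows: Iterable[int]) -> "GroupedAlignment":
        return GroupedAlignment([self.records[i] for i in rows])

    def slice_columns(self, start: int, end: int) -> "GroupedAlignment":
        """Columns ``start..end`` (1-based inclusive) as a new alignment."""
        if not (1 <= start <= end <= self.length):
            raise AlignmentError(f"interval {start}..{end} outside 1..{self.length}")
        return GroupedAlignment(
            [
                Record(r.haplotype_id, r.population, r.paralog,
                       r.residues[start - 1 : end])
                for r in self.records
            ]
        )


# -- I/O -------------------------------------------------------------------

METADATA_HEADER = ("haplotype_id", "population", "paralog")


def load_alignment(fasta_path: str | Path, metadata_path: str | Path) -> GroupedAlignment:
    """Read an aligned FASTA plus a tab-separated metadata table.

    The metadata file has a header line ``haplotype_id<TAB>population<TAB>paralog``
    and must cover every FASTA id.
    """
    meta: dict[str, tuple[str, str]] = {}
    with open(metadata_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[:3]) != METADATA_HEADER:
            raise MetadataError(
                f"metadata header {header!r} != {list(METADATA_HEADER)!r}"
            )
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise MetadataError(f"malformed metadata line: {line!r}")
            meta[parts[0]] = (parts[1], parts[2])

    records = []
    missing = []
    for seqrec in SeqIO.parse(str(fasta_path), "fasta"):
        if seqrec.id not in meta:
            missing.append(seqrec.id)
            continue
        pop, par = meta[seqrec.id]
        records.append(Record(seqrec.id, pop, par, str(seqrec.seq)))
    if missing:
        raise MetadataError(f"FASTA ids absent from metadata: {missing}")
    return GroupedAlignment(records)


def write_alignment(aln: GroupedAlignment, fasta_path: str | Path,
                    metadata_path: str | Path) -> None:
    """Write FASTA + metadata in the formats :func:`load_alignment` reads."""
    SeqIO.write(
        [SeqRecord(Seq(r.residues), id=r.haplotype_id, description="")
         for r in aln.records],
        str(fasta_path),
        "fasta",
    )
    with open(metadata_path, "w") as fh:
        fh.write("\t".join(METADATA_HEADER) + "\n")
        for r in aln.records:
            fh.write(f"{r.haplotype_id}\t{r.population}\t{r.paralog}\n")


# -- coding annotation -----------------------------------------------------


@dataclass(frozen=True)
class CodingMap:
    """Exon structure of the alignment: 1-based inclusive exon intervals,
    a reading-frame offset (0–2 bases to skip at the start of the
    concatenated exons) and a genetic-code table id (NCBI numbering,
    1 = standard)."""

    exons: tuple[tuple[int, int], ...]
    frame_offset: int = 0
    code_table: int = 1

    def __post_init__(self):
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"exon {start}..{end} is reversed")
            if start <= prev_end:
                raise ValueError("exons must be disjoint and ascending")
            prev_end = end
        if not 0 <= self.frame_offset <= 2:
            raise ValueError("frame_offset must be 0, 1 or 2")
        if (self.coding_length() - self.frame_offset) % 3 != 0:
            raise ValueError(
                "concatenated exon length minus frame_offset not divisible by 3"
            )

    def coding_length(self) -> int:
        return sum(end - start + 1 for start, end in self.exons)

    def coding_columns(self) -> np.ndarray:
        """1-based alignment columns that are inside codons, in codon order
        (the frame offset is dropped)."""
        cols = np.concatenate(
            [np.arange(start, end + 1) for start, end in self.exons]
        ) if self.exons else np.empty(0, dtype=int)
        cols = cols[self.frame_offset:]
        usable = (len(cols) // 3) * 3
        return cols[:usable]

    def noncoding_columns(self, length: int) -> np.ndarray:
        """1-based columns of a length-``length`` alignment not inside codons."""
        mask = np.ones(length + 1, dtype=bool)
        mask[0] = False
        mask[self.coding_columns()] = False
        return np.nonzero(mask)[0]

    def codon_columns(self) -> np.ndarray:
        """(n_codons, 3) array of 1-based columns for each codon."""
        cols = self.coding_columns()
        return cols.reshape(-1, 3)


def load_coding_map(path: str | Path) -> CodingMap:
    """Read a GFF-like tab file: lines ``exon<TAB>start<TAB>end``, with an
    optional ``frame<TAB>offset`` line and ``code_table<TAB>id`` line."""
    exons: list[tuple[int, int]] = []
    frame = 0
    table = 1
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "exon":
                exons.append((int(parts[1]), int(parts[2])))
            elif parts[0] == "frame":
                frame = int(parts[1])
            elif parts[0] == "code_table":
                table = int(parts[1])
    return CodingMap(tuple(exons), frame, table)


def write_coding_map(cmap: CodingMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for start, end in cmap.exons:
            fh.write(f"exon\t{start}\t{end}\n")
        fh.write(f"frame\t{cmap.frame_offset}\n")
        fh.write(f"code_table\t{cmap.code_table}\n")


# -- per-site classification ----------------------------------------------


@dataclass
class SiteTable:
    """Per-column summary of a grouped alignment.

    ``has_gap[j]`` — any included sequence has a gap in column j+1;
    ``has_missing[j]`` — any gap or N;
    ``polymorphic_overall[j]`` — at least two distinct non-missing states.
    ``states_by_group`` maps (population, paralog) to a list (one entry per
    column) of dicts ``state -> count`` over non-missing states.
    """

    length: int
    gap_policy: str
    has_gap: np.ndarray
    has_missing: np.ndarray
    polymorphic_overall: np.ndarray
    states_by_group: dict[tuple[str, str], list[dict[str, int]]]

    def included(self) -> np.ndarray:
        """Boolean mask of columns usable under the gap policy."""
        if self.gap_policy == "listwise":
            return ~self.has_missing
        return np.ones(self.length, dtype=bool)

    def fixed_between(self, population: str, paralog_a: str, paralog_b: str) -> np.ndarray:
        """Columns where both paralog groups of ``population`` are monomorphic
        (for non-missing states) and their states differ."""
        ga = self.states_by_group.get((population, paralog_a))
        gb = self.states_by_group.get((population, paralog_b))
        if ga is None or gb is None:
            raise KeyError(f"missing group for population {population!r}")
        out = np.zeros(self.length, dtype=bool)
        for j in range(self.length):
            sa, sb = ga[j], gb[j]
            if len(sa) == 1 and len(sb) == 1 and next(iter(sa)) != next(iter(sb)):
                out[j] = True
        return out


def classify_sites(aln: GroupedAlignment, gap_policy: str = "listwise") -> SiteTable:
    """Tabulate per-column states and polymorphism flags.

    Under the ``listwise`` policy (the default, matching how within-group
    polymorphism statistics are computed) a column with a gap or N anywhere
    is excluded from site counts; ``pairwise`` keeps every column and defers
    exclusion to each comparison.
    """
    if gap_policy not in ("listwise", "pairwise"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    m = aln.matrix
    has_gap = (m == GAP).any(axis=0)
    has_missing = ((m == GAP) | (m == NMISS)).any(axis=0)
    poly = np.zeros(aln.length, dtype=bool)
    for j in range(aln.length):
        states = set(m[:, j][m[:, j] < GAP].tolist())
        poly[j] = len(states) >= 2
    states_by_group: dict[tuple[str, str], list[dict[str, int]]] = {}
    for grp in aln.groups():
        rows = aln.group_indices(*grp)
        per_col: list[dict[str, int]] = []
        sub = m[rows]
        for j in range(aln.length):
            col = sub[:, j]
            col = col[col < GAP]
            vals, counts = np.unique(col, return_counts=True)
            per_col.append({ALPHABET[v]: int(c) for v, c in zip(vals, counts)})
        states_by_group[grp] = per_col
    return SiteTable(aln.length, gap_policy, has_gap, has_missing, poly,
                     states_by_group)


# -- consensus and translation ---------------------------------------------


def _codon_strings(aln: GroupedAlignment, rows: np.ndarray,
                   cmap: CodingMap) -> list[list[str]]:
    """Per sequence, the list of codon strings along the coding map."""
    cods = cmap.codon_columns()
    out = []
    for i in rows:
        res = aln.records[i].residues
        out.append(["".join(res[c - 1] for c in codon) for codon in cods])
    return out


def consensus_codons(aln: GroupedAlignment, rows: np.ndarray,
                     cmap: CodingMap) -> list[str]:
    """Majority-rule consensus codon per position over the given rows.

    Codons containing a gap or N are ignored for the vote; ties are broken
    lexicographically for determinism.  If no clean codon exists at a
    position the consensus codon is ``NNN``.
    """
    per_seq = _codon_strings(aln, rows, cmap)
    n_codons = len(per_seq[0]) if per_seq else 0
    cons = []
    for k in range(n_codons):
        counts: dict[str, int] = {}
        for seq in per_seq:
            cod = seq[k]
            if "-" in cod or "N" in cod:
                continue
            counts[cod] = counts.get(cod, 0) + 1
        if not counts:
            cons.append("NNN")
            continue
        best = max(counts.items(), key=lambda kv: (kv[1], [-ord(c) for c in kv[0]]))
        # max by count, then lexicographically smallest codon
        cons.append(best[0])
    return cons


def translate_and_identity(aln: GroupedAlignment, cmap: CodingMap,
                           group_a: tuple[str, str],
                           group_b: tuple[str, str]) -> float:
    """Percent amino-acid identity between two groups' consensus proteins.

    Each group's coding consensus is translated with the configured genetic
    code; positions where either consensus codon contains a gap or N, or
    translates to a stop, are skipped (stops with a warning).
    """
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[cmap.code_table]
    rows_a = aln.group_indices(*group_a)
    rows_b = aln.group_indices(*group_b)
    if len(rows_a) == 0 or len(rows_b) == 0:
        raise AlignmentError(f"empty group {group_a} or {group_b}")
    cons_a = consensus_codons(aln, rows_a, cmap)
    cons_b = consensus_codons(aln, rows_b, cmap)

    def aa(codon: str) -> str | None:
        if "-" in codon or "N" in codon:
            return None
        if codon in table.stop_codons:
            return "*"
        return table.forward_table[codon]

    matches = compared = 0
    for ca, cb in zip(cons_a, cons_b):
        ra, rb = aa(ca), aa(cb)
        if ra is None or rb is None:
            continue
        if ra == "*" or rb == "*":
            logger.warning("internal stop codon at a compared position; excluded")
            continue
        compared += 1
        if ra == rb:
            matches += 1
    if compared == 0:
        raise UndefinedResultError("all positions excluded from the comparison")
    return 100.0 * matches / compared


def translate_group_consensus(aln: GroupedAlignment, cmap: CodingMap,
                              group: tuple[str, str]) -> str:
    """Amino-acid string of a group's consensus coding sequence
    (gap/N codons as 'X', stops as '*')."""
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[cmap.code_table]
    rows = aln.group_indices(*group)
    out = []
    for cod in consensus_codons(aln, rows, cmap):
        if "-" in cod or "N" in cod:
            out.append("X")
        elif cod in table.stop_codons:
            out.append("*")
        else:
            out.append(table.forward_table[cod])
    return "".join(out)
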