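"""Readers and writers for every file the pipeline touches.

All sequence input is normalized to a DNA alphabet (U -> T) on read; the
folding and duplex modules convert back to RNA where base pairing is
evaluated.  Count tables keep the whole-library clean-read totals separately
from the per-feature counts, because a library contains many reads that are
not assigned to any profiled feature.  Coordinates are 0-based, half-open
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "SequenceRecord",
    "CountTable",
    "PathwayCollection",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_count_table",
    "write_count_table",
    "read_gmt",
    "read_edge_list",
    "write_edge_list",
    "read_config_yaml",
]

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")

COUNT_TABLE_HEADER = ("feature", "count_lib1", "count_lib2")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def normalize_alphabet(seq: str, *, context: str = "sequence") -> str:
    """Uppercase and convert U->T; reject characters outside {A,C,G,T,U,N}."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID_BASES
    if bad:
        raise FormatError(f"{context}: invalid characters {sorted(bad)!r}")
    return s


def reverse_complement(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (mature miRNA, precursor, UTR, genome)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.seq:
            raise FormatError(f"sequence record {self.id!r} with empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CountTable:
    """Feature-by-library read counts for a two-library comparison.

    ``totals`` are the whole-library clean-read counts (N1, N2), not the
    column sums: the libraries also contain reads outside the feature set.
    """

    feature_ids: tuple[str, ...]
    counts: tuple[tuple[int, int], ...]
    totals: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.feature_ids) != len(self.counts):
            raise FormatError("feature_ids and counts length mismatch")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise FormatError("duplicate feature ids in count table")
        if any(t <= 0 for t in self.totals):
            raise FormatError("library totals must be positive")
        if any(c1 < 0 or c2 < 0 for c1, c2 in self.counts):
            raise FormatError("negative count in count table")
        sums = (
            sum(c for c, _ in self.counts),
            sum(c for _, c in self.counts),
        )
        if sums[0] > self.totals[0] or sums[1] > self.totals[1]:
            raise FormatError(
                f"library totals {self.totals} smaller than column sums {sums}"
            )

    def __len__(self) -> int:
        return len(self.feature_ids)

    def __iter__(self):
        return iter(zip(self.feature_ids, self.counts))


@dataclass(frozen=True)
class PathwayCollection:
    """Pathway id -> member gene set, with optional display names."""

    pathways: Mapping[str, frozenset[str]]
    names: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, genes in self.pathways.items():
            if not genes:
                raise FormatError(f"pathway {pid!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.pathways)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA (wrapped or single-line), normalizing U->T.

    Duplicate ids, empty sequences and text before the first header are
    rejected with the offending line number.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        nonlocal header
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"line {header_line}: record {header!r} has no sequence")
        if header in seen:
            raise FormatError(f"line {header_line}: duplicate id {header!r}")
        seen.add(header)
        records.append(
            SequenceRecord(header, normalize_alphabet(seq, context=f"record {header!r}"))
        )
        chunks.clear()

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                header_line = lineno
                if not header:
                    raise FormatError(f"line {lineno}: empty FASTA header")
            else:
                if header is None:
                    raise FormatError(f"line {lineno}: sequence before first header")
                chunks.append(line)
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write single-line FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


# ---------------------------------------------------------------------------
# Count tables

def read_count_table(path: str | Path, totals: tuple[int, int]) -> CountTable:
    """Read a tab-separated (feature, count1, count2) table.

    A header line matching ``feature\\tcount_lib1\\tcount_lib2`` is optional.
    ``totals`` are the two library clean-read totals.
    """
    ids: list[str] = []
    counts: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and tuple(fields) == COUNT_TABLE_HEADER:
                continue
            if len(fields) != 3:
                raise FormatError(f"line {lineno}: expected 3 tab-separated fields")
            fid, c1s, c2s = fields
            try:
                c1, c2 = int(c1s), int(c2s)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer count") from exc
            if c1 < 0 or c2 < 0:
                raise FormatError(f"line {lineno}: negative count")
            ids.append(fid)
            counts.append((c1, c2))
    return CountTable(tuple(ids), tuple(counts), tuple(totals))


def write_count_table(table: CountTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(COUNT_TABLE_HEADER) + "\n")
        for fid, (c1, c2) in table:
            fh.write(f"{fid}\t{c1}\t{c2}\n")


# ---------------------------------------------------------------------------
# GMT pathway sets

def read_gmt(path: str | Path) -> PathwayCollection:
    """Read GMT: pathway id, description, then member genes, tab-separated."""
    pathways: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"line {lineno}: GMT line needs id, description and >=1 gene"
                )
            pid, desc, *genes = fields
            if pid in pathways:
                raise FormatError(f"line {lineno}: duplicate pathway id {pid!r}")
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"line {lineno}: pathway {pid!r} has no genes")
            pathways[pid] = frozenset(genes)
            names[pid] = desc
    return PathwayCollection(pathways, names)


# ---------------------------------------------------------------------------
# Edge lists

def write_edge_list(
    edges: Sequence[tuple[str, str, Mapping[str, object]]], path: str | Path
) -> None:
    """Write a tab-separated edge list with a header.

    Attribute keys must be consistent across edges; they become extra columns
    after ``source`` and ``target``.
    """
    keys: list[str] = []
    if edges:
        keys = sorted(edges[0][2])
        for _, _, attrs in edges:
            if sorted(attrs) != keys:
                raise FormatError("inconsistent attribute keys across edges")
    with open(path, "w") as fh:
        fh.write("\t".join(["source", "target", *keys]) + "\n")
        for src, dst, attrs in edges:
            fh.write("\t".join([src, dst, *(str(attrs[k]) for k in keys)]) + "\n")


def read_edge_list(path: str | Path) -> list[tuple[str, str, dict[str, str]]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["source", "target"]:
            raise FormatError("edge list must start with source/target columns")
        keys = header[2:]
        edges = []
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise FormatError(f"line {lineno}: wrong number of fields")
            edges.append((fields[0], fields[1], dict(zip(keys, fields[2:]))))
    return edges


# ---------------------------------------------------------------------------
# Config

def read_config_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise FormatError("pipeline config must be a YAML mapping")
    return data
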