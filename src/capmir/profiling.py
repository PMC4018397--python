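"""Library accounting and sequence-composition profiling.

Covers the bookkeeping a small-RNA sequencing report prints before any
statistics: per-library QC percentages (clean reads and the discard
categories), annotation-category breakdowns of the genome-mapped reads,
read-length distributions, and nucleotide-bias summaries (first base by
read length, and base composition per position along the read).

Percentages are rounded half-up to two decimals, which is the convention
the printed summary tables follow.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import SequenceRecord

__all__ = [
    "LibraryQC",
    "CategorySummary",
    "percent",
    "qc_percentages",
    "category_percentages",
    "length_distribution",
    "first_nucleotide_bias",
    "positional_nucleotide_bias",
]

NUCLEOTIDES = ("A", "C", "G", "U")

QC_DISCARD_CATEGORIES = (
    "adapter3_null",
    "insert_null",
    "adapter5_contaminants",
    "smaller_than_18nt",
    "polyA",
)

ANNOTATION_CATEGORIES = (
    "miRNA",
    "exon_antisense",
    "exon_sense",
    "intron_antisense",
    "intron_sense",
    "rRNA",
    "scRNA",
    "snRNA",
    "snoRNA",
    "tRNA",
    "unann",
)


def percent(count: int, total: int) -> float:
    """100*count/total, rounded half-up to 2 decimals (report convention)."""
    if total <= 0:
        raise ValueError("total must be positive")
    q = (Decimal(count) * 100 / Decimal(total)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return float(q)


@dataclass(frozen=True)
class LibraryQC:
    """Read-accounting of one library from raw reads to clean reads."""

    total_reads: int
    high_quality: int
    adapter3_null: int
    insert_null: int
    adapter5_contaminants: int
    smaller_than_18nt: int
    polyA: int
    clean_reads: int

    def __post_init__(self) -> None:
        if any(getattr(self, f.name) < 0 for f in fields(self)):
            raise ValueError("negative QC count")
        if self.high_quality > self.total_reads:
            raise ValueError("high_quality exceeds total_reads")
        discards = sum(getattr(self, c) for c in QC_DISCARD_CATEGORIES)
        if self.clean_reads + discards != self.high_quality:
            raise ValueError(
                "clean_reads + discards must equal high_quality "
                f"({self.clean_reads} + {discards} != {self.high_quality})"
            )


@dataclass(frozen=True)
class CategorySummary:
    """Unique-sequence and read counts per annotation category."""

    unique: Mapping[str, int]
    reads: Mapping[str, int]
    total_unique: int
    total_reads: int

    def __post_init__(self) -> None:
        if set(self.unique) != set(self.reads):
            raise ValueError("unique and reads must cover the same categories")
        if sum(self.unique.values()) != self.total_unique:
            raise ValueError("unique counts do not sum to total_unique")
        if sum(self.reads.values()) != self.total_reads:
            raise ValueError("read counts do not sum to total_reads")


def qc_percentages(qc: LibraryQC) -> pd.DataFrame:
    """Per-category percentages of high-quality reads (high_quality = 100%)."""
    if qc.high_quality == 0:
        raise ValueError("high_quality is zero")
    rows = [("high_quality", qc.high_quality, percent(qc.high_quality, qc.high_quality))]
    for cat in QC_DISCARD_CATEGORIES:
        rows.append((cat, getattr(qc, cat), percent(getattr(qc, cat), qc.high_quality)))
    rows.append(("clean_reads", qc.clean_reads, percent(qc.clean_reads, qc.high_quality)))
    return pd.DataFrame(rows, columns=["category", "count", "percent"])


def category_percentages(cs: CategorySummary) -> pd.DataFrame:
    """Unique-sequence and read percentages per annotation category."""
    if cs.total_unique <= 0 or cs.total_reads <= 0:
        raise ValueError("totals must be positive")
    rows = []
    for cat in cs.unique:
        rows.append(
            (
                cat,
                cs.unique[cat],
                percent(cs.unique[cat], cs.total_unique),
                cs.reads[cat],
                percent(cs.reads[cat], cs.total_reads),
            )
        )
    return pd.DataFrame(
        rows, columns=["category", "unique", "unique_percent", "reads", "read_percent"]
    )


def length_distribution(
    reads: Iterable[tuple[SequenceRecord, int]],
    length_range: tuple[int, int] = (18, 30),
) -> dict[object, float]:
    """Read-weighted length distribution; out-of-range lengths bin as 'other'.

    ``reads`` pairs each unique sequence with its read multiplicity.
    Fractions sum to 1 over the observed bins.
    """
    lo, hi = length_range
    counts: dict[object, int] = {}
    total = 0
    for rec, mult in reads:
        n = len(rec.seq)
        key: object = n if lo <= n <= hi else "other"
        counts[key] = counts.get(key, 0) + mult
        total += mult
    if total == 0:
        return {}
    return {k: v / total for k, v in sorted(counts.items(), key=lambda kv: str(kv[0]))}


def _as_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def first_nucleotide_bias(
    seqs: Iterable[SequenceRecord], length_range: tuple[int, int] = (18, 25)
) -> pd.DataFrame:
    """First-base composition per read length (rows sum to 1).

    Only lengths inside ``length_range`` with at least one sequence appear.
    """
    lo, hi = length_range
    tallies: dict[int, dict[str, int]] = {}
    for rec in seqs:
        n = len(rec.seq)
        if not lo <= n <= hi:
            continue
        first = _as_rna(rec.seq)[0]
        if first not in NUCLEOTIDES:
            continue  # N starts carry no bias information
        row = tallies.setdefault(n, dict.fromkeys(NUCLEOTIDES, 0))
        row[first] += 1
    data = []
    for n in sorted(tallies):
        total = sum(tallies[n].values())
        data.append([n] + [tallies[n][b] / total for b in NUCLEOTIDES])
    return pd.DataFrame(data, columns=["length", *NUCLEOTIDES]).set_index("length")


def positional_nucleotide_bias(
    seqs: Iterable[SequenceRecord], max_position: int = 24
) -> pd.DataFrame:
    """Base composition at positions 1..max_position (1-based), plus G+C.

    A sequence contributes to a position only if it is long enough; each
    row's four base fractions sum to 1. The ``GC`` column is the G+C
    fraction at that position.
    """
    tallies = [dict.fromkeys(NUCLEOTIDES, 0) for _ in range(max_position)]
    for rec in seqs:
        s = _as_rna(rec.seq)
        for i, base in enumerate(s[:max_position]):
            if base in NUCLEOTIDES:
                tallies[i][base] += 1
    data = []
    for i, row in enumerate(tallies):
        total = sum(row.values())
        if total == 0:
            continue
        fracs = [row[b] / total for b in NUCLEOTIDES]
        gc = (row["G"] + row["C"]) / total
        data.append([i + 1, *fracs, gc])
    return pd.DataFrame(data, columns=["position", *NUCLEOTIDES, "GC"]).set_index(
        "position"
    )
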