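"""Seeded generators for every input the pipeline consumes, with ground truth.

The generators emulate the two-stage caprine muscle design: two pooled
sequencing libraries (one per developmental stage, no replicates), log-normal
baseline miRNA abundances with a planted differentially expressed subset,
Poisson count sampling at a configurable depth, hairpin precursors with
controllable stem length and GC content embedded in a toy genome, 3'UTRs
with planted miRNA binding sites, and random pathway memberships with
designated enriched pathways.

Default scale is a desk-size stand-in for the study's ~1.56e7-read
libraries: depth 1e6 clean reads per library.  Counts are Poisson by
default, matching the no-replicate Poisson model the differential test
assumes; a negative-binomial dispersion is available for robustness
experiments.  Every generator is bit-reproducible given (seed, parameters)
and returns machine-checkable truth alongside the data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import CountTable, PathwayCollection, SequenceRecord, reverse_complement

__all__ = [
    "LibraryTruth",
    "HairpinTruth",
    "UTRTruth",
    "PathwayTruth",
    "simulate_libraries",
    "simulate_hairpin",
    "simulate_genome",
    "simulate_utrs",
    "simulate_pathways",
    "random_sequence",
    "write_truth_jsonl",
]

_DNA = np.array(list("ACGT"))

#: complement pairs and wobble partners, DNA spelling; used to plant true
#: mismatches that can be neither repaired nor read as G·U by the scanner
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_WOBBLE_PARTNER = {"G": "T", "T": "G"}


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def random_sequence(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    """Random DNA sequence with expected GC fraction ``gc``."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_DNA, size=length, p=p))


# ---------------------------------------------------------------------------
# Count libraries


@dataclass(frozen=True)
class LibraryTruth:
    """Ground truth for one simulated two-library count table."""

    feature_ids: tuple[str, ...]
    baseline_ppm: tuple[float, ...]
    effect_log2: tuple[float, ...]  # signed; 0 for null features
    de_labels: tuple[bool, ...]


def simulate_libraries(
    n_features: int = 500,
    depth1: int = 1_000_000,
    depth2: int = 1_000_000,
    de_fraction: float = 0.2,
    effect_log2: float = 3.0,
    baseline_median_ppm: float = 50.0,
    baseline_sigma: float = 1.5,
    dispersion: float = 0.0,
    seed: int = 0,
    prefix: str = "mir",
) -> tuple[CountTable, LibraryTruth]:
    """Two-library counts with a planted differentially expressed subset.

    Baselines (per million) are log-normal with the given median and
    log-scale sigma.  A DE feature's rate is split symmetrically:
    library 1 gets baseline * 2^(+effect/2) and library 2
    baseline * 2^(-effect/2) (sign flipped for down features), so the
    expected log2 ratio equals the signed effect.  ``dispersion`` > 0
    switches Poisson sampling to negative binomial with that 1/size
    overdispersion.
    """
    if depth1 <= 0 or depth2 <= 0:
        raise ValueError("depths must be positive")
    if not 0 <= de_fraction <= 1:
        raise ValueError("de_fraction must lie in [0, 1]")
    if n_features < 0 or effect_log2 < 0:
        raise ValueError("n_features and effect_log2 must be non-negative")
    rng = _rng(seed)
    ids = tuple(f"{prefix}-{i + 1:04d}" for i in range(n_features))
    baseline = baseline_median_ppm * np.exp(
        rng.normal(0.0, baseline_sigma, size=n_features)
    )
    n_de = round(de_fraction * n_features)
    de_idx = rng.choice(n_features, size=n_de, replace=False)
    signs = rng.choice([1.0, -1.0], size=n_de)
    effects = np.zeros(n_features)
    effects[de_idx] = effect_log2 * signs

    lam1 = baseline * depth1 / 1e6 * np.exp2(effects / 2)
    lam2 = baseline * depth2 / 1e6 * np.exp2(-effects / 2)
    if dispersion > 0:
        size = 1.0 / dispersion
        c1 = rng.negative_binomial(size, size / (size + lam1))
        c2 = rng.negative_binomial(size, size / (size + lam2))
    else:
        c1 = rng.poisson(lam1)
        c2 = rng.poisson(lam2)
    # library totals are whole-library clean-read counts; the profiled
    # features only account for part of them
    totals = (
        max(depth1, int(c1.sum())),
        max(depth2, int(c2.sum())),
    )
    table = CountTable(ids, tuple(zip(c1.tolist(), c2.tolist())), totals)
    truth = LibraryTruth(
        feature_ids=ids,
        baseline_ppm=tuple(baseline.tolist()),
        effect_log2=tuple(effects.tolist()),
        de_labels=tuple(bool(e != 0) for e in effects),
    )
    return table, truth


# ---------------------------------------------------------------------------
# Hairpins and a toy genome


@dataclass(frozen=True)
class HairpinTruth:
    """Layout of one constructed precursor (coordinates in the precursor)."""

    locus_id: str
    arm5: tuple[int, int]
    loop: tuple[int, int]
    arm3: tuple[int, int]
    mature: tuple[int, int]
    stem_len: int
    loop_len: int
    gc: float


def simulate_hairpin(
    stem_len: int = 28,
    loop_len: int = 6,
    gc: float = 0.6,
    mismatch_rate: float = 0.0,
    mature_len: int = 22,
    seed: int = 0,
    locus_id: str = "hp-1",
) -> tuple[SequenceRecord, HairpinTruth]:
    """A stem-loop precursor: 5' arm + loop + reverse complement of the arm.

    ``mismatch_rate`` mutates 3'-arm bases after the perfect complement is
    laid down, loosening the stem.  The mature sequence is the first
    ``mature_len`` bases of the 5' arm.
    """
    if stem_len < 16:
        raise ValueError("stem_len must be >= 16")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    if not 1 <= mature_len <= stem_len:
        raise ValueError("mature_len must fit inside the stem arm")
    rng = _rng(seed)
    arm5 = random_sequence(stem_len, rng, gc)
    loop = random_sequence(loop_len, rng, gc=0.2)  # AU-rich loop folds open
    arm3 = list(reverse_complement(arm5))
    if mismatch_rate > 0:
        for i in range(stem_len):
            if rng.random() < mismatch_rate:
                arm3[i] = str(rng.choice(_DNA[_DNA != arm3[i]]))
    seq = arm5 + loop + "".join(arm3)
    truth = HairpinTruth(
        locus_id=locus_id,
        arm5=(0, stem_len),
        loop=(stem_len, stem_len + loop_len),
        arm3=(stem_len + loop_len, 2 * stem_len + loop_len),
        mature=(0, mature_len),
        stem_len=stem_len,
        loop_len=loop_len,
        gc=gc,
    )
    return SequenceRecord(locus_id, seq), truth


@dataclass(frozen=True)
class GenomeTruth:
    """Embedded hairpin loci on the toy genome (plus strand coordinates)."""

    loci: tuple[dict, ...]


def simulate_genome(
    n_loci: int = 4,
    spacer_len: int = 400,
    stem_len: int = 28,
    loop_len: int = 6,
    gc: float = 0.6,
    mature_len: int = 22,
    seed: int = 0,
) -> tuple[SequenceRecord, list[dict], GenomeTruth]:
    """A toy genome with embedded hairpins and the matching hit table.

    Returns (genome record, hit rows, truth); each hit row has the keys the
    hairpin stage's tab-separated hit table uses: locus, start, end, strand,
    mature_id, mature_seq, genome_hits.  The mature read coordinates point
    at the first ``mature_len`` bases of the embedded 5' arm.
    """
    rng = _rng(seed)
    parts: list[str] = []
    pos = 0
    hits = []
    loci = []
    for i in range(n_loci):
        spacer = random_sequence(spacer_len, rng, gc=0.45)
        parts.append(spacer)
        pos += len(spacer)
        hp, truth = simulate_hairpin(
            stem_len, loop_len, gc, 0.0, mature_len,
            seed=int(rng.integers(2**31)), locus_id=f"locus-{i + 1}",
        )
        parts.append(hp.seq)
        mstart = pos + truth.mature[0]
        mend = pos + truth.mature[1]
        mature_seq = hp.seq[truth.mature[0] : truth.mature[1]]
        hits.append(
            {
                "locus": truth.locus_id,
                "start": mstart,
                "end": mend,
                "strand": "+",
                "mature_id": f"novel-mir-{i + 1}",
                "mature_seq": mature_seq,
                "genome_hits": 1,
            }
        )
        loci.append({"locus": truth.locus_id, "precursor_start": pos,
                     "precursor_end": pos + len(hp.seq), **asdict(truth)})
        pos += len(hp.seq)
    parts.append(random_sequence(spacer_len, rng, gc=0.45))
    genome = SequenceRecord("toy-genome", "".join(parts))
    return genome, hits, GenomeTruth(tuple(loci))


# ---------------------------------------------------------------------------
# UTRs with planted target sites


@dataclass(frozen=True)
class UTRTruth:
    """Planted site coordinates and mutation positions per UTR."""

    sites: tuple[dict, ...]  # utr_id, mirna_id, start, end, mutated_positions


def simulate_utrs(
    mirnas: Sequence[SequenceRecord],
    n_utrs: int = 20,
    sites_per_utr: int = 1,
    mutation_count: int = 0,
    utr_len: int = 300,
    seed: int = 0,
    prefix: str = "gene",
) -> tuple[list[SequenceRecord], UTRTruth]:
    """Random-background UTRs with planted reverse-complement target sites.

    Each planted site is the reverse complement of a randomly chosen miRNA
    carrying exactly ``mutation_count`` mismatches; mutated bases are chosen
    so the duplex position is a true mismatch (neither Watson-Crick nor
    G·U), and the mutated miRNA positions (1-based from the miRNA 5' end)
    are recorded in the truth.
    """
    if not mirnas:
        raise ValueError("need at least one miRNA")
    max_m = max(len(m.seq) for m in mirnas)
    if utr_len < max_m + 10:
        raise ValueError("utr_len too short for the miRNA set")
    rng = _rng(seed)
    records = []
    site_truths = []
    for u in range(n_utrs):
        utr_id = f"{prefix}-{u + 1:03d}"
        seq = list(random_sequence(utr_len, rng, gc=0.5))
        taken: list[tuple[int, int]] = []
        for _ in range(sites_per_utr):
            mir = mirnas[int(rng.integers(len(mirnas)))]
            m = len(mir.seq)
            site = list(reverse_complement(mir.seq.upper().replace("U", "T")))
            mutated: list[int] = []
            if mutation_count > 0:
                pos_choices = rng.choice(m, size=mutation_count, replace=False)
                for p in sorted(int(x) for x in pos_choices):
                    # site index pairing miRNA position p (0-based): m-1-p
                    si = m - 1 - p
                    mir_base = mir.seq.upper().replace("U", "T")[p]
                    forbidden = {site[si], _COMPLEMENT[mir_base]}
                    wob = _WOBBLE_PARTNER.get(mir_base)
                    if wob:
                        forbidden.add(wob)
                    choices = [b for b in "ACGT" if b not in forbidden]
                    site[si] = str(rng.choice(np.array(choices)))
                    mutated.append(p + 1)
            # place without overlapping previously planted sites
            for _attempt in range(100):
                start = int(rng.integers(0, utr_len - m + 1))
                if all(start + m <= s or start >= e for s, e in taken):
                    break
            else:
                continue
            taken.append((start, start + m))
            seq[start : start + m] = site
            site_truths.append(
                {
                    "utr_id": utr_id,
                    "mirna_id": mir.id,
                    "start": start,
                    "end": start + m,
                    "mutated_positions": mutated,
                }
            )
        records.append(SequenceRecord(utr_id, "".join(seq)))
    return records, UTRTruth(tuple(site_truths))


# ---------------------------------------------------------------------------
# Pathways


@dataclass(frozen=True)
class PathwayTruth:
    enriched: tuple[str, ...]


def simulate_pathways(
    genes: Sequence[str],
    n_pathways: int = 50,
    size_range: tuple[int, int] = (10, 40),
    enriched_pathways: int = 0,
    favored_genes: Sequence[str] = (),
    odds: float = 20.0,
    seed: int = 0,
) -> tuple[PathwayCollection, PathwayTruth]:
    """Random pathway memberships, optionally oversampling favored genes.

    The first ``enriched_pathways`` pathways draw members with weight
    ``odds`` on ``favored_genes`` (e.g. the simulated DE-target genes) and
    weight 1 elsewhere; the rest sample uniformly.
    """
    lo, hi = size_range
    if lo < 2:
        raise ValueError("pathway sizes must be >= 2")
    if lo > hi or hi > len(genes):
        raise ValueError("invalid size range for the gene universe")
    rng = _rng(seed)
    genes = list(genes)
    favored = set(favored_genes)
    pathways: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    enriched_ids = []
    weights_enriched = np.array([odds if g in favored else 1.0 for g in genes])
    weights_enriched = weights_enriched / weights_enriched.sum()
    for i in range(n_pathways):
        pid = f"pw-{i + 1:03d}"
        size = int(rng.integers(lo, hi + 1))
        if i < enriched_pathways and favored:
            members = rng.choice(
                len(genes), size=size, replace=False, p=weights_enriched
            )
            enriched_ids.append(pid)
        else:
            members = rng.choice(len(genes), size=size, replace=False)
        pathways[pid] = frozenset(genes[j] for j in members)
        names[pid] = f"simulated pathway {i + 1}"
    return PathwayCollection(pathways, names), PathwayTruth(tuple(enriched_ids))


# ---------------------------------------------------------------------------
# Truth serialization


def write_truth_jsonl(truth, path: str | Path) -> None:
    """Write any truth dataclass as JSON lines (one field per line)."""
    payload = asdict(truth) if not isinstance(truth, dict) else truth
    with open(path, "w") as fh:
        for key, value in payload.items():
            fh.write(json.dumps({key: value}) + "\n")
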