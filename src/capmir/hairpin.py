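"""Novel-miRNA candidate screening.

A candidate locus is a short read mapped to the genome; its precursor window
is the read plus 150 nt of flanking sequence on each side.  The window is
folded (``capmir.fold``) and the candidate judged by a battery of filters
modelled on the criteria miRNA discovery pipelines apply to putative
precursors:

1. at most 10 genomic hits for the read,
2. mature length between 16 and 30 nt,
3. folding free energy below -18 kcal/mol,
4. the mature sequence resides in a stem arm (at most 4 of its bases fall in
   terminal loops; the arm is the side holding the majority of its paired
   bases),
5. MFEI = |AMFE| / GC% above 0.85, where AMFE = 100 * MFE / length,
6. a single dominant stem-loop (exactly one terminal loop in the MFE
   structure).

The verdict is the conjunction of all six flags.  The battery is a
deterministic surrogate for the machine-learned pseudo-precursor screening
step some published pipelines add on top (candidate reports carry a
``mipred_surrogate`` marker for this reason), and every threshold is
configuration-exposed: the
absolute energies of the simplified folding model differ from full
Turner-parameter folders, so recalibration against a reference folder is
legitimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .fold import fold_mfe, pair_table
from .io import SequenceRecord, reverse_complement, to_rna

__all__ = [
    "HairpinThresholds",
    "HairpinCandidate",
    "extract_flanks",
    "mfei_metrics",
    "terminal_loops",
    "candidate_precursor",
    "evaluate_candidate",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_FLANK = 150


@dataclass(frozen=True)
class HairpinThresholds:
    """Filter battery thresholds (energies in kcal/mol)."""

    genome_hits_max: int = 10
    mature_len_range: tuple[int, int] = (16, 30)
    mfe_max: float = -18.0
    max_loop_bases: int = 4  # mature bases tolerated inside terminal loops
    mfei_min: float = 0.85


DEFAULT_THRESHOLDS = HairpinThresholds()


@dataclass(frozen=True)
class HairpinCandidate:
    """A folded precursor window with all filter evidence attached."""

    locus_id: str
    precursor: str
    structure: str
    mfe: float
    amfe: float
    mfei: float
    gc_percent: float
    mature_start: int  # 0-based half-open, within the precursor window
    mature_end: int
    arm: str  # 5p | 3p | loop
    genome_hits: int
    flags: Mapping[str, bool] = field(default_factory=dict)

    @property
    def verdict(self) -> bool:
        return all(self.flags.values())


def extract_flanks(
    genome: SequenceRecord,
    start: int,
    end: int,
    strand: str = "+",
    flank: int = DEFAULT_FLANK,
) -> tuple[str, int, int]:
    """Precursor window [start-flank, end+flank) clipped to the sequence.

    Returns (window sequence, window start, window end) in plus-strand
    coordinates; for a minus-strand hit the sequence is reverse-complemented
    so the mature read always appears in window orientation.
    """
    if not 0 <= start < end <= len(genome.seq):
        raise ValueError(
            f"hit [{start},{end}) outside genome {genome.id!r} of length {len(genome.seq)}"
        )
    lo = max(0, start - flank)
    hi = min(len(genome.seq), end + flank)
    if lo >= hi:
        raise ValueError("empty precursor window")
    window = genome.seq[lo:hi]
    if strand == "-":
        window = reverse_complement(window)
    elif strand != "+":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    return window, lo, hi


def mfei_metrics(mfe: float, seq: str) -> tuple[float, float, float]:
    """(AMFE, MFEI, GC%) for a precursor.

    AMFE = 100 * MFE / length; MFEI = |AMFE| / GC%.  MFEI is reported as 0
    for a GC-free sequence (the candidate then fails the MFEI filter).
    """
    if not seq:
        raise ValueError("empty sequence")
    if mfe > 0:
        raise ValueError("MFE must be <= 0")
    s = seq.upper()
    gc_percent = 100.0 * sum(1 for b in s if b in "GC") / len(s)
    amfe = 100.0 * mfe / len(s)
    mfei = abs(amfe) / gc_percent if gc_percent > 0 else 0.0
    return amfe, mfei, gc_percent


def terminal_loops(structure: str) -> list[tuple[int, int]]:
    """Half-open intervals of terminal (hairpin) loops in a dot-bracket.

    A terminal loop is the unpaired stretch directly enclosed by a pair with
    no further pairs inside it.
    """
    partner = pair_table(structure)
    loops = []
    for i, j in enumerate(partner):
        if j <= i:
            continue
        if all(partner[k] == -1 for k in range(i + 1, j)):
            loops.append((i + 1, j))
    return loops


def candidate_precursor(
    window: str,
    mature_start: int,
    mature_end: int,
    max_precursor_len: int = 150,
) -> tuple[int, int]:
    """Trim a flanked window to the stem-loop enclosing the mature read.

    A mapped read is extended with long genomic flanks before folding, and
    the flanks fold into structures of their own; the putative precursor is
    only the stem-loop the mature read sits in.  Among pairs that enclose
    the mature read and exactly one terminal loop, the widest whose span
    stays within ``max_precursor_len`` wins (occasional long-range flank
    pairs enclose the hairpin through large interior loops without adding
    terminal loops, and would otherwise balloon the precursor); the
    interval is widened to cover any overhanging mature bases.  Returns the
    whole window when no such stem-loop exists — the filter battery then
    judges, and fails, the window itself.
    """
    structure, _ = fold_mfe(to_rna(window))
    partner = pair_table(structure)
    loops = terminal_loops(structure)
    spans = []
    for i, j in enumerate(partner):
        if j <= i:
            continue
        inside = sum(1 for lo, hi in loops if i < lo and hi <= j)
        overlaps = mature_start < j + 1 and mature_end > i
        if inside == 1 and overlaps:
            spans.append((i, j))
    capped = [s for s in spans if s[1] - s[0] + 1 <= max_precursor_len]
    pool = capped or spans
    if not pool:
        return 0, len(window)
    best = max(pool, key=lambda s: s[1] - s[0]) if capped else min(
        pool, key=lambda s: s[1] - s[0]
    )
    a = min(best[0], mature_start)
    b = max(best[1] + 1, mature_end)
    return a, b


def _mature_arm(
    structure: str, mature_start: int, mature_end: int
) -> tuple[str, int]:
    """Arm assignment and loop-residence count for the mature read.

    Returns (arm, loop_bases): arm is '5p' if the majority of the mature's
    paired bases have partners downstream (3') of themselves, '3p' for the
    converse, 'loop' if no mature base is paired; loop_bases counts mature
    bases inside terminal loops.
    """
    partner = pair_table(structure)
    loops = terminal_loops(structure)
    loop_bases = sum(
        1
        for k in range(mature_start, mature_end)
        for (lo, hi) in loops
        if lo <= k < hi
    )
    five = sum(
        1 for k in range(mature_start, mature_end) if partner[k] > k
    )
    three = sum(
        1 for k in range(mature_start, mature_end) if 0 <= partner[k] < k
    )
    if five == 0 and three == 0:
        return "loop", loop_bases
    return ("5p" if five >= three else "3p"), loop_bases


def evaluate_candidate(
    locus_id: str,
    window: str,
    mature: str,
    genome_hits: int,
    thresholds: HairpinThresholds = DEFAULT_THRESHOLDS,
) -> HairpinCandidate:
    """Fold a precursor window and apply the six-filter battery.

    ``mature`` must occur as a substring of ``window`` (first occurrence is
    scored).  All sequences may be spelled with T or U.
    """
    win = window.upper().replace("U", "T")
    mat = mature.upper().replace("U", "T")
    pos = win.find(mat)
    if pos < 0:
        raise ValueError(f"mature read not found in window for locus {locus_id!r}")
    mstart, mend = pos, pos + len(mat)

    structure, mfe = fold_mfe(to_rna(win))
    amfe, mfei, gc_percent = mfei_metrics(mfe, win)
    arm, loop_bases = _mature_arm(structure, mstart, mend)
    n_loops = len(terminal_loops(structure))

    lo_len, hi_len = thresholds.mature_len_range
    flags = {
        "genome_hits": genome_hits <= thresholds.genome_hits_max,
        "mature_length": lo_len <= len(mat) <= hi_len,
        "mfe": mfe < thresholds.mfe_max,
        "stem_residence": loop_bases <= thresholds.max_loop_bases and arm != "loop",
        "mfei": mfei > thresholds.mfei_min,
        "single_stem_loop": n_loops == 1,
    }
    return HairpinCandidate(
        locus_id=locus_id,
        precursor=win,
        structure=structure,
        mfe=mfe,
        amfe=amfe,
        mfei=mfei,
        gc_percent=gc_percent,
        mature_start=mstart,
        mature_end=mend,
        arm=arm,
        genome_hits=genome_hits,
        flags=flags,
    )
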