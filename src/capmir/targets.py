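"""Rule-based miRNA -> 3'UTR target prediction.

Sites are scored by aligning the miRNA 5'->3' against the reverse-complement
sense of a UTR window (antiparallel duplex) and summing per-position
penalties in the plant-rule tradition: 1.0 per mismatch, 0.5 per G·U wobble,
2.0 per bulged base, with every cost doubled at miRNA positions 2-13
(1-based from the miRNA 5' end, covering the seed and central pairing
region).  A candidate site is kept when

* total penalty <= 4.0,
* no more than 2 consecutive mismatches,
* no mismatch at miRNA positions 10-11 (the cleavage-site positions; a
  wobble is tolerated there, a true mismatch is not).

Bulges are limited to one unpaired base on either strand and at most one per
site, so windows of length m-1, m and m+1 are scanned at every UTR offset.
``scan_utr`` evaluates all windows through a vectorized formulation of the
same arithmetic as the scalar ``duplex_score`` (all costs are multiples of
0.5, so the two paths agree exactly), then reconstructs alignments only for
windows under the penalty cutoff.

A duplex free energy (sum of nearest-neighbor stacking terms over
consecutively paired positions, from the folding engine's parameter table)
is attached for ranking and reporting; it is not a filter.

Alignment state strings use one character per miRNA position plus one per
bulged site base: ``M`` match, ``G`` G·U wobble, ``X`` mismatch, ``B``
bulge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fold import STACK_ENERGY, _PAIR_ID
from .io import SequenceRecord

__all__ = [
    "TargetRules",
    "TargetSite",
    "duplex_score",
    "duplex_energy",
    "scan_utr",
    "DEFAULT_RULES",
]


@dataclass(frozen=True)
class TargetRules:
    """Penalty table and filters for target-site scoring."""

    mismatch: float = 1.0
    wobble: float = 0.5
    bulge: float = 2.0
    double_from: int = 2  # 1-based miRNA positions with doubled costs
    double_to: int = 13
    max_penalty: float = 4.0
    max_consecutive_mismatches: int = 2
    no_mismatch_positions: tuple[int, ...] = (10, 11)  # 1-based
    max_bulges: int = 1


DEFAULT_RULES = TargetRules()

_RNA_PAIRS = {"AU", "UA", "CG", "GC"}
_WOBBLE = {"GU", "UG"}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}

# state class of (miRNA base, site base): 0 = match, 1 = wobble, 2 = mismatch
_STATE_TABLE = np.full((4, 4), 2, dtype=np.int64)
for _a, _b in _RNA_PAIRS:
    _STATE_TABLE[_BASE_INDEX[_a], _BASE_INDEX[_b]] = 0
for _a, _b in _WOBBLE:
    _STATE_TABLE[_BASE_INDEX[_a], _BASE_INDEX[_b]] = 1


@dataclass(frozen=True)
class TargetSite:
    """One predicted miRNA binding site on a 3'UTR."""

    mirna_id: str
    transcript_id: str
    utr_start: int  # 0-based half-open on the UTR
    utr_end: int
    penalty: float
    duplex_mfe: float
    alignment: str


def _as_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _check_alphabet(seq: str, what: str) -> str:
    s = _as_rna(seq)
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"{what}: invalid characters {sorted(bad)!r}")
    return s


def _pair_state(a: str, b: str) -> str:
    duo = a + b
    if duo in _RNA_PAIRS:
        return "M"
    if duo in _WOBBLE:
        return "G"
    return "X"


def _weights(m: int, rules: TargetRules) -> np.ndarray:
    pos = np.arange(1, m + 1)
    return np.where((pos >= rules.double_from) & (pos <= rules.double_to), 2.0, 1.0)


def _state_cost(state: str, rules: TargetRules) -> float:
    return {"M": 0.0, "G": rules.wobble, "X": rules.mismatch, "B": rules.bulge}[state]


def duplex_score(
    mirna: str, site: str, rules: TargetRules = DEFAULT_RULES
) -> tuple[float, str]:
    """Best penalty and alignment of a miRNA against one site window.

    ``site`` is the UTR subsequence in its natural 5'->3' orientation; the
    miRNA pairs antiparallel, so miRNA position p faces site base
    len(site)-1-p (shifted across a bulge).  Window length may be m-1
    (one miRNA base bulged), m (no bulge) or m+1 (one site base bulged).
    Among the admissible bulge placements the minimum-penalty alignment is
    returned; bulge costs are charged at the miRNA position that follows
    the bulged base.
    """
    m = _check_alphabet(mirna, "miRNA")
    s = _check_alphabet(site, "site")
    t = s[::-1]  # site read 3'->5', aligned index-wise with the miRNA
    n, L = len(m), len(t)
    if L not in (n - 1, n, n + 1):
        raise ValueError(f"site window length {L} incompatible with miRNA length {n}")
    w = _weights(n, rules)

    candidates: list[tuple[float, str]] = []
    if L == n:
        states = [_pair_state(m[p], t[p]) for p in range(n)]
        pen = sum(_state_cost(st, rules) * w[p] for p, st in enumerate(states))
        candidates.append((pen, "".join(states)))
    elif L == n + 1:
        # one site base bulged out at t-index g; miRNA base p faces t[p]
        # before the bulge and t[p+1] from it onward
        for g in range(L):
            states = []
            pen = 0.0
            for p in range(n):
                tp = p if p < g else p + 1
                st = _pair_state(m[p], t[tp])
                states.append(st)
                pen += _state_cost(st, rules) * w[p]
            pen += rules.bulge * w[min(g, n - 1)]
            states.insert(g, "B")
            candidates.append((pen, "".join(states)))
    else:  # L == n - 1: miRNA base g bulged
        for g in range(n):
            states = []
            pen = rules.bulge * w[g]
            for p in range(n):
                if p == g:
                    states.append("B")
                    continue
                tp = p if p < g else p - 1
                st = _pair_state(m[p], t[tp])
                states.append(st)
                pen += _state_cost(st, rules) * w[p]
            candidates.append((pen, "".join(states)))

    return min(candidates, key=lambda c: (c[0], c[1]))


def duplex_energy(mirna: str, site: str, alignment: str) -> float:
    """Intermolecular stacking energy (kcal/mol) over the aligned duplex.

    Sums nearest-neighbor stacking terms for every run of consecutive paired
    positions (match or wobble); a fully unpaired alignment scores 0.
    """
    m = _check_alphabet(mirna, "miRNA")
    t = _check_alphabet(site, "site")[::-1]
    site_bulge = len(t) == len(m) + 1
    per_mirna: list[int | None] = []  # pair-type id per miRNA position
    mi = ti = 0
    for st in alignment:
        if st == "B":
            if site_bulge:
                ti += 1
            else:
                per_mirna.append(None)
                mi += 1
            continue
        if st in ("M", "G"):
            per_mirna.append(_PAIR_ID[m[mi] + t[ti]])
        else:
            per_mirna.append(None)
        mi += 1
        ti += 1
    total = 0
    for a, b in zip(per_mirna, per_mirna[1:]):
        if a is not None and b is not None:
            total += int(STACK_ENERGY[a, b])
    return total / 100.0


def _passes_filters(alignment: str, site_bulge: bool, rules: TargetRules) -> bool:
    run = 0
    for st in alignment:
        if st == "X":
            run += 1
            if run > rules.max_consecutive_mismatches:
                return False
        else:
            run = 0  # bulges and wobbles break a mismatch run
    pos = 0  # 1-based miRNA position; a site bulge is not a miRNA position
    for st in alignment:
        if st == "B" and site_bulge:
            continue
        pos += 1
        if st == "X" and pos in rules.no_mismatch_positions:
            return False
    return True


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX[b] for b in seq), dtype=np.int64, count=len(seq))


def _penalty_lattice(
    q: np.ndarray, u: np.ndarray, rules: TargetRules
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimum penalty per UTR start for window lengths m, m+1, m-1.

    Built from one cost matrix C[s, p] = weighted cost of miRNA base p
    against utr[s + m - 1 - p]; a one-base bulge on either strand only
    shifts which row of C a prefix or suffix of the alignment reads, so all
    bulge placements reduce to prefix-sum arithmetic over C.
    """
    m, n_utr = len(q), len(u)
    S = n_utr - m + 1  # number of length-m windows
    costs = np.array([0.0, rules.wobble, rules.mismatch])
    w = _weights(m, rules)

    # rows s = -1 .. S  (stored at index s+1); clipped indices are only read
    # where they cancel out of the arithmetic
    rows = np.arange(-1, S + 1)
    pos = np.arange(m)
    idx = np.clip(rows[:, None] + (m - 1 - pos)[None, :], 0, n_utr - 1)
    C = costs[_STATE_TABLE[q[None, :], u[idx]]] * w[None, :]
    P = np.concatenate([np.zeros((C.shape[0], 1)), np.cumsum(C, axis=1)], axis=1)
    total = P[:, -1]

    def row(s: int) -> int:
        return s + 1

    pen_m = total[row(0) : row(S)].copy()  # no-bulge penalty per start

    # site bulge: starts 0..S-2 (window length m+1), gap g = 0..m
    if S >= 2:
        s_arr = np.arange(0, S - 1)
        g = np.arange(m + 1)
        wB = rules.bulge * w[np.minimum(g, m - 1)]
        pen = (
            P[row(1) + s_arr[:, None], g[None, :]]
            + (total[row(0) + s_arr][:, None] - P[row(0) + s_arr[:, None], g[None, :]])
            + wB[None, :]
        )
        pen_site = pen.min(axis=1)
    else:
        pen_site = np.empty(0)

    # miRNA bulge: starts 0..S (window length m-1), bulged miRNA base g = 0..m-1
    if m >= 2:
        s_arr = np.arange(0, S + 1)
        g = np.arange(m)
        pen = (
            P[row(-1) + s_arr[:, None], g[None, :]]
            + (total[row(0) + s_arr][:, None] - P[row(0) + s_arr[:, None], (g + 1)[None, :]])
            + (rules.bulge * w[g])[None, :]
        )
        pen_mir = pen.min(axis=1)
    else:
        pen_mir = np.empty(0)

    return pen_m, pen_site, pen_mir


def scan_utr(
    mirna: SequenceRecord,
    utr: SequenceRecord,
    rules: TargetRules = DEFAULT_RULES,
) -> list[TargetSite]:
    """All retained target sites of one miRNA on one UTR, best first.

    Every UTR offset is scored at window lengths m-1, m, m+1; sites passing
    the penalty cutoff and the structural filters are returned sorted by
    (penalty, duplex energy, position).  A UTR shorter than the miRNA
    yields an empty list.
    """
    m = len(mirna.seq)
    utr_rna = _check_alphabet(utr.seq, f"UTR {utr.id!r}")
    mir_rna = _check_alphabet(mirna.seq, f"miRNA {mirna.id!r}")
    if len(utr_rna) < m or m < 2:
        return []
    q, u = _encode(mir_rna), _encode(utr_rna)
    pen_m, pen_site, pen_mir = _penalty_lattice(q, u, rules)

    candidates: list[tuple[int, int]] = []  # (start, window length)
    for s in np.flatnonzero(pen_m <= rules.max_penalty):
        candidates.append((int(s), m))
    for s in np.flatnonzero(pen_site <= rules.max_penalty):
        candidates.append((int(s), m + 1))
    for s in np.flatnonzero(pen_mir <= rules.max_penalty):
        candidates.append((int(s), m - 1))

    sites: list[TargetSite] = []
    for start, L in candidates:
        window = utr.seq[start : start + L]
        penalty, alignment = duplex_score(mirna.seq, window, rules)
        if penalty > rules.max_penalty:
            continue
        if not _passes_filters(alignment, site_bulge=(L == m + 1), rules=rules):
            continue
        energy = duplex_energy(mirna.seq, window, alignment)
        sites.append(
            TargetSite(
                mirna_id=mirna.id,
                transcript_id=utr.id,
                utr_start=start,
                utr_end=start + L,
                penalty=penalty,
                duplex_mfe=energy,
                alignment=alignment,
            )
        )
    sites.sort(key=lambda s: (s.penalty, s.duplex_mfe, s.utr_start, s.utr_end))
    return sites
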