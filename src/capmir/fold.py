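"""Minimum-free-energy RNA secondary structure by dynamic programming.

A self-contained, oracle-verifiable folding engine built around a simplified
nearest-neighbor model: stacking free energies for Watson-Crick and G·U
pairs, length-dependent penalties for hairpin, bulge and internal loops, and
an affine multibranch-loop cost.  Dangling ends, terminal-AU penalties,
special tetraloops and coaxial stacking are deliberately omitted, so absolute
energies are not comparable with full Turner-parameter folders; the engine
exists so that every energy the pipeline reports can be recomputed
independently by exhaustive enumeration on small inputs.

Energies are kept as integers in units of 0.01 kcal/mol throughout, which
makes the dynamic program, the traceback and the independent structure
evaluator agree exactly (no float-tolerance comparisons).

The recursion is the classic pseudoknot-free decomposition (V/WM/W): V(i,j)
is the minimum energy given i pairs j, built from hairpin closure, helix
stacking, bounded-size interior loops and multibranch closure; WM handles
multiloop segments and W the exterior loop.  Interior loops larger than
``MAX_INTERIOR`` unpaired bases are not searched (standard practice).
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "fold_mfe",
    "structure_energy",
    "pair_table",
    "MIN_HAIRPIN",
    "MAX_INTERIOR",
]

MIN_HAIRPIN = 3  # minimum unpaired bases closed by a hairpin loop
MAX_INTERIOR = 15  # largest interior/bulge loop searched by the DP
INF = 2**31

_BASES = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

# pair type ids; -1 = not pairable
_PAIRS = ("AU", "UA", "CG", "GC", "GU", "UG")
_PAIR_ID = {p: i for i, p in enumerate(_PAIRS)}


def _pair_id(a: str, b: str) -> int:
    return _PAIR_ID.get(a + b, -1)


def _build_stack_table() -> np.ndarray:
    """6x6 stacking energies (0.01 kcal/mol), outer pair x inner pair.

    Watson-Crick/Watson-Crick values adapted from published nearest-neighbor
    free energies at 37 C (rounded); stacks involving a G·U wobble are given
    a uniform mild stabilization.  The physical symmetry
    E(p, q) = E(reverse(q), reverse(p)) is enforced by construction.
    """
    base = {
        ("AU", "AU"): -93,
        ("AU", "UA"): -110,
        ("UA", "AU"): -133,
        ("CG", "AU"): -211,
        ("CG", "UA"): -208,
        ("GC", "AU"): -235,
        ("GC", "UA"): -224,
        ("CG", "GC"): -236,
        ("GC", "CG"): -342,
        ("GC", "GC"): -326,
    }
    rev = {"AU": "UA", "UA": "AU", "CG": "GC", "GC": "CG", "GU": "UG", "UG": "GU"}
    table = np.zeros((6, 6), dtype=np.int64)
    wobble = {"GU", "UG"}
    for p in _PAIRS:
        for q in _PAIRS:
            if p in wobble and q in wobble:
                e = -40
            elif p in wobble or q in wobble:
                e = -50
            else:
                e = base.get((p, q))
                if e is None:
                    e = base[(rev[q], rev[p])]
            table[_PAIR_ID[p], _PAIR_ID[q]] = e
    # sanity: physical symmetry must hold
    for p in _PAIRS:
        for q in _PAIRS:
            assert table[_PAIR_ID[p], _PAIR_ID[q]] == table[_PAIR_ID[rev[q]], _PAIR_ID[rev[p]]]
    return table


STACK_ENERGY = _build_stack_table()

_HAIRPIN_BASE = {3: 540, 4: 560, 5: 570, 6: 540, 7: 600, 8: 550, 9: 640}
_BULGE_BASE = {1: 380, 2: 280, 3: 320, 4: 360, 5: 400, 6: 440}
_INTERNAL_BASE = {2: 150, 3: 160, 4: 170, 5: 200, 6: 210}

# affine multibranch loop: a + b per branch (closing pair included) + c per
# unpaired base
MULTI_A = 460
MULTI_B = 40
MULTI_C = 10


def hairpin_energy(size: int) -> int:
    if size < MIN_HAIRPIN:
        raise ValueError(f"hairpin loop of size {size} < {MIN_HAIRPIN}")
    if size in _HAIRPIN_BASE:
        return _HAIRPIN_BASE[size]
    return _HAIRPIN_BASE[9] + round(108 * math.log(size / 9))


def bulge_energy(size: int) -> int:
    if size < 1:
        raise ValueError("bulge loop needs >= 1 unpaired base")
    if size in _BULGE_BASE:
        return _BULGE_BASE[size]
    return _BULGE_BASE[6] + round(108 * math.log(size / 6))


def internal_energy(size: int) -> int:
    if size < 2:
        raise ValueError("internal loop needs >= 2 unpaired bases")
    if size in _INTERNAL_BASE:
        return _INTERNAL_BASE[size]
    return _INTERNAL_BASE[6] + round(108 * math.log(size / 6))


def _encode(seq: str) -> str:
    """Uppercase RNA spelling; accepts T, rejects anything else."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - set(_BASES)
    if bad:
        raise ValueError(f"folding alphabet is A/C/G/U(T); got {sorted(bad)!r}")
    return s


def pair_table(structure: str) -> list[int]:
    """Partner index per position (-1 = unpaired) from dot-bracket."""
    partner = [-1] * len(structure)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            partner[j], partner[i] = i, j
        elif ch != ".":
            raise ValueError(f"invalid structure character {ch!r}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return partner


def _loop_children(partner: list[int], i: int, j: int) -> tuple[list[tuple[int, int]], int]:
    """Branches and unpaired count directly inside pair (i, j)."""
    branches = []
    unpaired = 0
    k = i + 1
    while k < j:
        if partner[k] == -1:
            unpaired += 1
            k += 1
        else:
            branches.append((k, partner[k]))
            k = partner[k] + 1
    return branches, unpaired


def structure_energy_int(seq: str, structure: str) -> int:
    """Energy (0.01 kcal/mol) of a given structure under the model.

    Evaluates the loop decomposition directly, independent of the dynamic
    program; used as the cross-check that any structure the DP emits carries
    exactly its claimed energy.
    """
    s = _encode(seq)
    if len(structure) != len(s):
        raise ValueError("structure and sequence length differ")
    partner = pair_table(structure)
    total = 0
    for i, j in enumerate(partner):
        if j <= i:
            continue
        if _pair_id(s[i], s[j]) < 0:
            raise ValueError(f"forbidden pair {s[i]}{s[j]} at ({i},{j})")
        branches, unpaired = _loop_children(partner, i, j)
        if not branches:
            total += hairpin_energy(unpaired)
        elif len(branches) == 1:
            (k, l) = branches[0]
            left, right = k - i - 1, j - l - 1
            if left == 0 and right == 0:
                total += int(
                    STACK_ENERGY[_pair_id(s[i], s[j]), _pair_id(s[k], s[l])]
                )
            elif left == 0 or right == 0:
                total += bulge_energy(left + right)
            else:
                total += internal_energy(left + right)
        else:
            total += MULTI_A + MULTI_B * (len(branches) + 1) + MULTI_C * unpaired
    return total


def structure_energy(seq: str, structure: str) -> float:
    """Energy of a structure in kcal/mol."""
    return structure_energy_int(seq, structure) / 100.0


def _interior_penalties() -> np.ndarray:
    pen = np.full((MAX_INTERIOR + 1, MAX_INTERIOR + 1), INF, dtype=np.int64)
    for l1 in range(MAX_INTERIOR + 1):
        for l2 in range(MAX_INTERIOR + 1 - l1):
            if l1 == 0 and l2 == 0:
                continue  # that case is helix stacking
            size = l1 + l2
            pen[l1, l2] = bulge_energy(size) if (l1 == 0 or l2 == 0) else internal_energy(size)
    return pen


_INTERIOR_PEN = _interior_penalties()


def fold_mfe(seq: str) -> tuple[str, float]:
    """Minimum-free-energy structure and energy (kcal/mol) of ``seq``.

    Returns a dot-bracket string and the MFE; the open chain scores 0, so
    the MFE is never positive.  Deterministic: ties are resolved by a fixed
    traceback order (hairpin, stack, interior by loop size, multibranch by
    leftmost split).
    """
    s = _encode(seq)
    n = len(s)
    if n == 0:
        raise ValueError("empty sequence")
    min_span = MIN_HAIRPIN + 1
    if n < min_span + 1:
        return "." * n, 0.0

    ptype = np.full((n, n), -1, dtype=np.int64)
    for i in range(n):
        for j in range(i + min_span, n):
            ptype[i, j] = _pair_id(s[i], s[j])

    hp = np.array([0] * MIN_HAIRPIN + [hairpin_energy(k) for k in range(MIN_HAIRPIN, n)],
                  dtype=np.int64) if n > MIN_HAIRPIN else np.zeros(n, dtype=np.int64)

    V = np.full((n, n), INF, dtype=np.int64)
    WM = np.full((n, n), INF, dtype=np.int64)

    for i in range(n - min_span - 1, -1, -1):
        for j in range(i + min_span, n):
            pt = ptype[i, j]
            if pt >= 0:
                best = hp[j - i - 1]
                # helix stacking on (i+1, j-1)
                if j - i - 2 > MIN_HAIRPIN and ptype[i + 1, j - 1] >= 0:
                    cand = V[i + 1, j - 1] + STACK_ENERGY[pt, ptype[i + 1, j - 1]]
                    if cand < best:
                        best = cand
                # interior/bulge loops (l1, l2), 1 <= l1+l2 <= MAX_INTERIOR
                for l1 in range(0, min(MAX_INTERIOR, j - i - min_span - 2) + 1):
                    k = i + 1 + l1
                    l2max = min(MAX_INTERIOR - l1, j - 1 - (k + min_span))
                    if l2max < 0:
                        break
                    lo = j - 1 - l2max
                    seg = V[k, lo : j][::-1]  # l2 = 0..l2max
                    cand = (seg + _INTERIOR_PEN[l1, : l2max + 1]).min()
                    if cand < best:
                        best = int(cand)
                # multibranch closure
                if j - i > 2 * min_span + 2:
                    a1 = WM[i + 1, i + 1 : j - 1]
                    a2 = WM[i + 2 : j, j - 1]
                    cand = int((a1 + a2).min()) + MULTI_A + 2 * MULTI_B
                    if cand < best:
                        best = cand
                V[i, j] = best

            # WM
            wm = INF
            if WM[i + 1, j] != INF:
                wm = WM[i + 1, j] + MULTI_C
            if WM[i, j - 1] != INF and WM[i, j - 1] + MULTI_C < wm:
                wm = WM[i, j - 1] + MULTI_C
            if V[i, j] != INF and V[i, j] + MULTI_B < wm:
                wm = V[i, j] + MULTI_B
            if j - i >= 2 * min_span + 1:
                b1 = WM[i, i : j]
                b2 = WM[i + 1 : j + 1, j]
                split = int((b1 + b2).min())
                if split < wm:
                    wm = split
            WM[i, j] = wm

    # exterior loop: W[k] = MFE of prefix s[:k]
    W = np.zeros(n + 1, dtype=np.int64)
    for j in range(min_span, n):
        w = W[j]
        vals = W[: j - min_span + 1] + V[: j - min_span + 1, j]
        if vals.size:
            m = int(vals.min())
            if m < w:
                w = m
        W[j + 1] = w

    structure = ["."] * n
    _traceback(s, ptype, hp, V, WM, W, structure)
    mfe = int(W[n])
    return "".join(structure), mfe / 100.0


def _traceback(s, ptype, hp, V, WM, W, structure) -> None:
    n = len(s)
    min_span = MIN_HAIRPIN + 1
    pairs: list[tuple[int, int]] = []
    stack: list[tuple[str, int, int]] = [("W", 0, n)]

    while stack:
        kind, i, j = stack.pop()
        if kind == "W":
            # j = prefix length
            while j > 0:
                if W[j] == W[j - 1]:
                    j -= 1
                    continue
                found = False
                for i0 in range(0, j - min_span):
                    if W[i0] + V[i0, j - 1] == W[j]:
                        stack.append(("V", i0, j - 1))
                        j = i0
                        found = True
                        break
                assert found, "external traceback failed"
        elif kind == "V":
            pairs.append((i, j))
            e = V[i, j]
            if e == hp[j - i - 1]:
                continue
            pt = ptype[i, j]
            if (
                j - i - 2 > MIN_HAIRPIN
                and ptype[i + 1, j - 1] >= 0
                and V[i + 1, j - 1] + STACK_ENERGY[pt, ptype[i + 1, j - 1]] == e
            ):
                stack.append(("V", i + 1, j - 1))
                continue
            done = False
            for size in range(1, MAX_INTERIOR + 1):
                if done:
                    break
                for l1 in range(0, size + 1):
                    l2 = size - l1
                    k, l = i + 1 + l1, j - 1 - l2
                    if k + min_span > l or l >= n:
                        continue
                    if V[k, l] != INF and V[k, l] + _INTERIOR_PEN[l1, l2] == e:
                        stack.append(("V", k, l))
                        done = True
                        break
            if done:
                continue
            for k in range(i + 1, j - 1):
                if (
                    WM[i + 1, k] != INF
                    and WM[k + 1, j - 1] != INF
                    and MULTI_A + 2 * MULTI_B + WM[i + 1, k] + WM[k + 1, j - 1] == e
                ):
                    stack.append(("WM", i + 1, k))
                    stack.append(("WM", k + 1, j - 1))
                    done = True
                    break
            assert done, "pair traceback failed"
        else:  # WM
            e = WM[i, j]
            while True:
                if V[i, j] != INF and V[i, j] + MULTI_B == e:
                    stack.append(("V", i, j))
                    break
                if WM[i + 1, j] != INF and WM[i + 1, j] + MULTI_C == e:
                    i += 1
                    e = WM[i, j]
                    continue
                if WM[i, j - 1] != INF and WM[i, j - 1] + MULTI_C == e:
                    j -= 1
                    e = WM[i, j]
                    continue
                found = False
                for k in range(i, j):
                    if WM[i, k] != INF and WM[k + 1, j] != INF and WM[i, k] + WM[k + 1, j] == e:
                        stack.append(("WM", i, k))
                        stack.append(("WM", k + 1, j))
                        found = True
                        break
                assert found, "multiloop traceback failed"
                break

    for a, b in pairs:
        structure[a], structure[b] = "(", ")"
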