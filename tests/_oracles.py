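"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route independent of the production
code path it checks: exhaustive structure enumeration vs the folding DP,
direct log-space tail summation vs the incomplete-beta exact test, exact
integer combinatorics vs the scipy hypergeometric, and a hand-rolled BH
step-up vs the statsmodels adjustment.
"""

from __future__ import annotations

import math

import numpy as np

from capmir.fold import MIN_HAIRPIN, _pair_id


def enumerate_structures(seq: str):
    """All pseudoknot-free structures of a short RNA (dot-bracket strings).

    Pairs obey the folding engine's pairing rules and the minimum hairpin
    loop; intended for len(seq) <= 13.
    """
    s = seq.upper().replace("T", "U")
    n = len(s)

    def rec(positions: tuple[int, ...]):
        if not positions:
            yield ()
            return
        i = positions[0]
        rest = positions[1:]
        for sub in rec(rest):
            yield sub
        for idx, j in enumerate(rest):
            if j - i - 1 >= MIN_HAIRPIN and _pair_id(s[i], s[j]) >= 0:
                for a in rec(tuple(rest[:idx])):
                    for b in rec(tuple(rest[idx + 1 :])):
                        yield ((i, j),) + a + b

    for pairing in rec(tuple(range(n))):
        db = ["."] * n
        for i, j in pairing:
            db[i], db[j] = "(", ")"
        yield "".join(db)


def brute_audic_p(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided exact-test p by direct summation of the conditional law."""
    t = n2 / n1
    logt, log1pt = math.log(t), math.log1p(t)

    def pmf(k: int) -> float:
        return math.exp(
            k * logt
            + math.lgamma(x + k + 1)
            - math.lgamma(x + 1)
            - math.lgamma(k + 1)
            - (x + k + 1) * log1pt
        )

    lower = sum(pmf(k) for k in range(0, y + 1))
    upper, k = 0.0, y
    while True:
        term = pmf(k)
        upper += term
        k += 1
        if k > y + 10 and (term < upper * 1e-17 or k > x + y + 5000):
            break
    return min(1.0, 2 * min(lower, upper))


def brute_audic_tails(x: int, ratio: float, kmax: int) -> tuple[np.ndarray, np.ndarray]:
    """Lower/upper tail P(Y<=y), P(Y>=y) for y = 0..kmax, by log-sum-exp.

    Vectorized form of the same direct summation, for grid checks.
    """
    k = np.arange(kmax + 1)
    from scipy.special import gammaln

    logpmf = (
        k * math.log(ratio)
        + gammaln(x + k + 1)
        - gammaln(x + 1)
        - gammaln(k + 1)
        - (x + k + 1) * math.log1p(ratio)
    )
    lower = np.logaddexp.accumulate(logpmf)
    upper = np.logaddexp.accumulate(logpmf[::-1])[::-1]
    return np.exp(lower), np.exp(upper)


def brute_hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for a hypergeometric draw, by exact integer combinatorics."""
    denom = math.comb(N, n)
    total = 0
    for kk in range(max(k, 0, n - (N - K)), min(K, n) + 1):
        total += math.comb(K, kk) * math.comb(N - K, n - kk)
    return total / denom


def bh_step_up(pvals) -> list[float]:
    """Hand-rolled Benjamini-Hochberg step-up, input order preserved."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adjusted[i] = running
    return adjusted
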