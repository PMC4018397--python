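"""Two-library differential expression by the exact Poisson (Audic-Claverie) test.

The experimental design pools many animals into one sequencing library per
developmental stage (fetal, FC; six-month, SMC), so there are no replicates:
each feature is summarized by a single count per library.  Under Poisson
sampling, conditioning on the combined count x+y gives the exact law of the
second library's count

    p(y | x) = (N2/N1)^y * (x+y)! / (x! y! (1 + N2/N1)^(x+y+1)),

which is a negative-binomial distribution in y with r = x+1 and success
probability N1/(N1+N2).  The two-sided p-value doubles the smaller tail and
caps at 1.  Expression is reported as normalized expression (NE), the count
scaled by the library's clean-read total, in transcripts per million;
fold change is log2(NE1/NE2).

Multiple testing is corrected with Benjamini-Hochberg; the differential
call uses FDR <= 0.001 together with |log2 ratio| >= 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountTable

__all__ = [
    "DETestResult",
    "normalize",
    "log2_fold_change",
    "audic_claverie_p",
    "bh_fdr",
    "classify_de",
    "scatter_class",
    "de_table",
    "de_frame",
]

#: pseudocount (transcripts per million) added to a zero NE before a ratio
ZERO_NE_PSEUDOCOUNT = 0.01

DEFAULT_FDR_MAX = 0.001
DEFAULT_LOG2_MIN = 1.0


@dataclass(frozen=True)
class DETestResult:
    """Exact-test outcome for one feature across the two libraries."""

    feature_id: str
    x: int
    y: int
    n1: int
    n2: int
    ne1: float
    ne2: float
    log2fc: float  # NaN when both counts are zero (excluded from calling)
    p: float
    fdr: float
    de_class: str  # up | down | not_de
    scatter_class: str  # fold>2 | 1/2<fold<=2 | fold<=1/2


def normalize(count: int, total: int) -> float:
    """Normalized expression in transcripts per million: 1e6 * count/total."""
    if total <= 0:
        raise ValueError("library total must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return 1e6 * count / total


def log2_fold_change(
    ne1: float, ne2: float, pseudo: float = ZERO_NE_PSEUDOCOUNT
) -> float:
    """log2(NE1/NE2); a zero NE gets the pseudocount, both-zero is NaN."""
    if ne1 < 0 or ne2 < 0:
        raise ValueError("NE values must be non-negative")
    if pseudo <= 0:
        raise ValueError("pseudocount must be positive")
    if ne1 == 0 and ne2 == 0:
        return math.nan
    a = ne1 if ne1 > 0 else pseudo
    b = ne2 if ne2 > 0 else pseudo
    return math.log2(a / b)


def audic_claverie_p(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided exact test that a feature's rate differs between libraries.

    Conditional on x, Y follows a negative binomial with r = x+1 and
    p = N1/(N1+N2); the p-value is 2*min(P(Y<=y), P(Y>=y)) capped at 1.
    Computed through the regularized incomplete beta function, stable at
    library-scale counts.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    if x == 0 and y == 0:
        return 1.0  # no reads observed anywhere: no evidence of a difference
    psucc = n1 / (n1 + n2)
    lower = stats.nbinom.cdf(y, x + 1, psucc)  # P(Y <= y)
    upper = stats.nbinom.sf(y - 1, x + 1, psucc)  # P(Y >= y)
    p = min(1.0, 2.0 * min(lower, upper))
    # both tails contain the observation, so p is exactly 1 at the symmetric
    # center; absorb float noise in the incomplete-beta evaluation there
    return 1.0 if p >= 1.0 - 1e-9 else float(p)


def bh_fdr(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, input order preserved."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1) | np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1].tolist()


def classify_de(
    log2fc: float,
    fdr: float,
    fdr_max: float = DEFAULT_FDR_MAX,
    log2_min: float = DEFAULT_LOG2_MIN,
) -> str:
    """Significance call: FDR <= fdr_max and |log2 ratio| >= log2_min."""
    if math.isnan(log2fc):
        return "not_de"
    if fdr <= fdr_max and log2fc >= log2_min:
        return "up"
    if fdr <= fdr_max and log2fc <= -log2_min:
        return "down"
    return "not_de"


def scatter_class(
    ne1: float, ne2: float, pseudo: float = ZERO_NE_PSEUDOCOUNT
) -> str:
    """Fold-change class used to colour the expression scatter plot."""
    if ne1 == 0 and ne2 == 0:
        raise ValueError("scatter class undefined when both NE are zero")
    a = ne1 if ne1 > 0 else pseudo
    b = ne2 if ne2 > 0 else pseudo
    r = a / b
    if r > 2:
        return "fold>2"
    if r > 0.5:
        return "1/2<fold<=2"
    return "fold<=1/2"


def de_table(
    table: CountTable,
    fdr_max: float = DEFAULT_FDR_MAX,
    log2_min: float = DEFAULT_LOG2_MIN,
    pseudo: float = ZERO_NE_PSEUDOCOUNT,
) -> list[DETestResult]:
    """Run the full per-feature test battery over a two-library count table.

    FDR is adjusted across all tested features; features with zero counts in
    both libraries keep p = 1 and an undefined (NaN) fold change and are
    never called differential.
    """
    n1, n2 = table.totals
    pvals = [audic_claverie_p(c1, c2, n1, n2) for _, (c1, c2) in table]
    fdrs = bh_fdr(pvals)
    results = []
    for (fid, (c1, c2)), p, q in zip(table, pvals, fdrs):
        ne1, ne2 = normalize(c1, n1), normalize(c2, n2)
        lfc = log2_fold_change(ne1, ne2, pseudo)
        de = classify_de(lfc, q, fdr_max, log2_min)
        sc = (
            scatter_class(ne1, ne2, pseudo)
            if not (ne1 == 0 and ne2 == 0)
            else "1/2<fold<=2"
        )
        results.append(DETestResult(fid, c1, c2, n1, n2, ne1, ne2, lfc, p, q, de, sc))
    return results


def de_frame(results: Iterable[DETestResult]) -> pd.DataFrame:
    """Tabular view of DE results (the on-disk report format)."""
    cols = [
        "feature_id", "x", "y", "n1", "n2", "ne1", "ne2",
        "log2fc", "p", "fdr", "de_class", "scatter_class",
    ]
    return pd.DataFrame([[getattr(r, c) for c in cols] for r in results], columns=cols)
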