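"""Likelihood-ratio tests, FDR correction, and rank correlation.

The branch-site decision rule follows the fixed chi-square(1) 5% critical
value of 3.84 ("supported" only when the statistic strictly exceeds it),
rather than the mixture-of-chi-squares null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

BRANCH_SITE_CRITICAL_VALUE = round(float(scipy.stats.chi2.isf(0.05, df=1)), 2)

_NEG_TOL = 1e-6


class SelectionTestError(ValueError):
    pass


@dataclass(frozen=True)
class LrtResult:
    statistic: float
    df: int
    p_value: float
    adjusted_p: float | None = None
    decision: str | None = None

    def adjusted(self, adjusted_p: float, decision: str | None = None) -> "LrtResult":
        if adjusted_p < self.p_value - 1e-12:
            raise SelectionTestError("adjusted p cannot be below the raw p")
        return LrtResult(self.statistic, self.df, self.p_value, adjusted_p, decision)


def lrt(L_alt: float, L_null: float, df: int) -> LrtResult:
    """2*(L_alt - L_null) against a chi-square upper tail.

    Negative statistics within optimizer slack are clipped to zero; larger
    negatives indicate a failed alternative optimization and raise.
    """
    if not (np.isfinite(L_alt) and np.isfinite(L_null)):
        raise SelectionTestError("log-likelihoods must be finite")
    if df < 1:
        raise SelectionTestError("df must be a positive integer")
    stat = 2.0 * (L_alt - L_null)
    if stat < -_NEG_TOL:
        raise SelectionTestError(
            f"alternative worse than null (2dL = {stat:.6g}): check optimization"
        )
    stat = max(stat, 0.0)
    p = float(scipy.stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return LrtResult(statistic=stat, df=df, p_value=min(p, 1.0))


def branch_site_decision(result: LrtResult) -> str:
    """'supported' iff the statistic strictly exceeds 3.84 (chi2_1, 5%).

    A statistic exactly at the critical value does not support the selection
    model; a small tolerance keeps the strict comparison robust to
    floating-point representation of 2*dL.
    """
    if result.statistic > BRANCH_SITE_CRITICAL_VALUE + 1e-9:
        return "supported"
    return "unsupported"


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise SelectionTestError("pvalues must be a non-empty 1-d vector")
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise SelectionTestError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def rank_correlation(x, y) -> tuple[float, float]:
    """Spearman's rho (average ranks for ties) with a t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise SelectionTestError("input vectors differ in length")
    if x.size < 3:
        raise SelectionTestError("need at least 3 paired observations")
    rho, p = scipy.stats.spearmanr(x, y)
    return float(rho), float(p)
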