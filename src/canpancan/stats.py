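"""Shared statistical kernels: Fisher exact tests, BH correction, rank-sum tests.

These thin wrappers fix the conventions used throughout the pipeline
(sidedness, degenerate-table handling, exact-vs-approximate switching) so
every module tests identically shaped hypotheses the same way.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fisher_exact",
    "bh_adjust",
    "wilcoxon_rank_sum",
    "odds_ratio_haldane",
]


def fisher_exact(table, alternative: str = "two-sided") -> float:
    """Fisher exact p value on a 2x2 count table.

    A table with a zero margin carries no information about association; by
    convention it returns p = 1 (scipy agrees, but the case is made explicit
    here because degenerate tables are routine in sparse mutation data).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("negative counts in contingency table")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        return 1.0
    return float(sps.fisher_exact(t, alternative=alternative)[1])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q values (same order as input)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> float:
    """Two-sample Wilcoxon (Mann-Whitney) p value.

    Exact null distribution when both groups have n <= 25 and the pooled data
    carry no ties; otherwise the normal approximation with tie correction
    and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 25 and y.size <= 25 and no_ties) else "asymptotic"
    return float(sps.mannwhitneyu(x, y, alternative=alternative, method=method).pvalue)


def odds_ratio_haldane(table) -> float:
    """Odds ratio with Haldane-Anscombe 0.5 correction when any cell is 0.

    Display-only companion to :func:`fisher_exact`; p values remain exact.
    """
    t = np.asarray(table, dtype=float)
    if (t == 0).any():
        t = t + 0.5
    return float((t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0]))
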