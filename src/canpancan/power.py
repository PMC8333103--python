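"""Sample-size and power calculations.

Closed-form binomial detection power (probability of observing a mutation at
least once), simulation-based power of two-sample Fisher exact tests on
binomial prevalences (with the p1 = p2 x OR construction and its cap rule),
simulation-based power of two-sample Wilcoxon tests on normal shifts, and the
pooled-SD standardized effect size used to drive the Wilcoxon simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from ._streams import child_rng

__all__ = [
    "PowerConfig",
    "binomial_detection_power",
    "construct_prevalences",
    "fisher_power_sim",
    "wilcoxon_power_sim",
    "standardized_effect_size",
]


@dataclass(frozen=True)
class PowerConfig:
    alpha: float = 0.05
    n1: int = 20
    n2: int = 20
    p2: float = 0.1
    odds_ratio: float = 2.0
    reps: int = 500           # Fisher simulation default
    wilcoxon_reps: int = 10_000
    effect_size: float = 0.93  # mean shift of the high group (sigma = 1)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n1 < 1 or self.n2 < 1 or self.reps < 1 or self.wilcoxon_reps < 1:
            raise ValueError("sample sizes and reps must be >= 1")
        if not 0 <= self.p2 <= 1:
            raise ValueError("p2 must be in [0, 1]")


def binomial_detection_power(p: float, n: int) -> float:
    """Probability of detecting a mutation at least once: 1 - (1 - p)^n."""
    if not 0 <= p <= 1:
        raise ValueError("prevalence must be in [0, 1]")
    if n < 1:
        raise ValueError("sample size must be >= 1")
    return 1.0 - (1.0 - p) ** n


def construct_prevalences(p2: float, odds_ratio: float) -> tuple:
    """(p1, p2) with p1 = p2 x OR; if p1 > 1 then p1 = 1 and p2 = p1 / OR."""
    if odds_ratio < 1:
        raise ValueError("construction assumes enrichment in group 1 (OR >= 1)")
    p1 = p2 * odds_ratio
    if p1 > 1:
        p1 = 1.0
        p2 = p1 / odds_ratio
    return p1, p2


def fisher_power_sim(config: PowerConfig, alternative: str = "two-sided") -> dict:
    """Monte-Carlo power of the two-sample Fisher exact test.

    Each replicate draws mutant counts Binomial(n1, p1) and Binomial(n2, p2)
    and tests the 2x2 table at ``config.alpha``. p values are cached per
    distinct count pair, so large replicate counts stay cheap. Returns the
    rejection fraction and its Monte-Carlo standard error.
    """
    rng = child_rng(config.seed, "fisher-power")
    p1, p2 = construct_prevalences(config.p2, config.odds_ratio)
    x1 = rng.binomial(config.n1, p1, size=config.reps)
    x2 = rng.binomial(config.n2, p2, size=config.reps)
    cache: dict = {}
    reject = 0
    for a, b in zip(x1, x2):
        key = (int(a), int(b))
        if key not in cache:
            table = [[key[0], config.n1 - key[0]], [key[1], config.n2 - key[1]]]
            cache[key] = sps.fisher_exact(table, alternative=alternative)[1]
        if cache[key] <= config.alpha:
            reject += 1
    power = reject / config.reps
    se = float(np.sqrt(power * (1 - power) / config.reps))
    return {"power": power, "se": se, "p1": p1, "p2": p2, "reps": config.reps}


def _ranksum_p_vectorized(high: np.ndarray, low: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum normal-approximation p values, one per row pair.

    Continuous draws make ties measure-zero, so the plain normal
    approximation with continuity correction matches scipy's asymptotic
    Mann-Whitney test.
    """
    reps, n1 = high.shape
    n2 = low.shape[1]
    pooled = np.concatenate([high, low], axis=1)
    ranks = sps.rankdata(pooled, axis=1)
    u1 = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    sigma = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
    z = (np.abs(u1 - mu) - 0.5) / sigma
    return 2 * sps.norm.sf(z)


def wilcoxon_power_sim(config: PowerConfig) -> dict:
    """Monte-Carlo power of the two-sample Wilcoxon test for a normal shift.

    Per replicate: group 1 ~ N(effect_size, 1) at n1, group 2 ~ N(0, 1) at
    n2, two-sided rank-sum test at ``config.alpha``. Returns rejection
    fraction and Monte-Carlo SE.
    """
    rng = child_rng(config.seed, "wilcoxon-power")
    reps = config.wilcoxon_reps
    high = rng.normal(config.effect_size, 1.0, size=(reps, config.n1))
    low = rng.normal(0.0, 1.0, size=(reps, config.n2))
    p = _ranksum_p_vectorized(high, low)
    power = float((p <= config.alpha).mean())
    se = float(np.sqrt(power * (1 - power) / reps))
    return {"power": power, "se": se, "reps": reps,
            "effect_size": config.effect_size}


def standardized_effect_size(group_high, group_low) -> float:
    """(mean_high - mean_low) / pooled SD with (n1-1, n2-1) weighting.

    Callers pass log10-transformed TMB values when estimating the effect
    size that drives :func:`wilcoxon_power_sim`.
    """
    x = np.asarray(group_high, dtype=float)
    y = np.asarray(group_low, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 values")
    s2 = (((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1))
          / (x.size + y.size - 2))
    if s2 == 0:
        raise ValueError("zero pooled standard deviation")
    return float((x.mean() - y.mean()) / np.sqrt(s2))
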