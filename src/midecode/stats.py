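"""Chance-level thresholds and paired nonparametric tests.

A classifier that guesses still scores above 1/K on a finite trial set; the
better-than-chance threshold is the upper confidence bound of the guessing
accuracy given the number of test trials and classes, here via the
adjusted-Wald (Agresti–Coull) construction with an exact-binomial alternative.
Paired comparisons between conditions use the Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats


@dataclass
class ChanceThreshold:
    n_trials: int
    n_classes: int
    alpha: float
    threshold_pct: float


def chance_threshold(
    n_trials: int, n_classes: int = 2, alpha: float = 0.05, method: str = "adjusted-wald"
) -> ChanceThreshold:
    """Upper bound of the chance-accuracy confidence interval, in percent.

    ``adjusted-wald``: one-sided Agresti–Coull bound with z = Φ⁻¹(1-α) around
    the expected guessing rate p₀ = 1/K. ``binomial``: exact binomial
    (1-α)-quantile of the guessing success count divided by n.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    p0 = 1.0 / n_classes
    if method == "adjusted-wald":
        z = sstats.norm.ppf(1.0 - alpha)
        x = n_trials * p0
        n_adj = n_trials + z**2
        p_adj = (x + z**2 / 2.0) / n_adj
        upper = p_adj + z * np.sqrt(p_adj * (1.0 - p_adj) / n_adj)
    elif method == "binomial":
        upper = sstats.binom.ppf(1.0 - alpha, n_trials, p0) / n_trials
    else:
        raise ValueError(f"unknown method {method!r}")
    return ChanceThreshold(
        n_trials=n_trials,
        n_classes=n_classes,
        alpha=alpha,
        threshold_pct=100.0 * min(float(upper), 1.0),
    )


@dataclass
class PairedTestResult:
    statistic: float
    p_value: float
    n_pairs: int


def wilcoxon_signed_rank(x, y) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped (Wilcoxon's convention). The exact null
    distribution is used for n ≤ 25 without ties; otherwise the normal
    approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero (degenerate input)")
    has_ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = sstats.wilcoxon(d, alternative="two-sided", method=method)
    return PairedTestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue), n_pairs=n
    )
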