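"""Shared statistical machinery.

Benjamini-Hochberg false-discovery-rate control (classic step-up rule),
the Monte Carlo test for an imbalance in the proportion of units changing
in each direction, and the recording-instability correlation control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from pairedstim._rng import as_generator


@dataclass
class PValueFamily:
    """One family of hypotheses under FDR control at level q.

    ``rejected`` follows the step-up rule: reject hypotheses 1..k where
    k = max{i : p_(i) <= i q / m}, so the rejected set is always a prefix of
    the sorted p-values.
    """

    labels: list
    raw_p: np.ndarray
    q: float
    rejected: np.ndarray
    adjusted: np.ndarray


def benjamini_hochberg(raw_p, q: float = 0.05, labels=None) -> PValueFamily:
    """Classic (1995) Benjamini-Hochberg step-up procedure."""
    raw_p = np.asarray(raw_p, dtype=float)
    if raw_p.size == 0:
        return PValueFamily(labels=[], raw_p=raw_p, q=q,
                            rejected=np.zeros(0, dtype=bool), adjusted=raw_p.copy())
    if np.any((raw_p < 0) | (raw_p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, adjusted, _, _ = multipletests(raw_p, alpha=q, method="fdr_bh")
    if labels is None:
        labels = list(range(raw_p.size))
    return PValueFamily(labels=list(labels), raw_p=raw_p, q=q,
                        rejected=rejected, adjusted=adjusted)


def proportion_mc_test(
    n_increase: int,
    n_decrease: int,
    n_total: int,
    n_mc: int = 10000,
    seed=0,
) -> float:
    """Two-sided Monte Carlo p for an imbalance of increases vs decreases.

    Null model: among the units that changed at all, each direction is a
    fair coin; unchanged units stay fixed.  The statistic is the absolute
    deviation of the increase count from its null mean, and the p-value uses
    the add-one permutation estimator (so it is never exactly zero).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_increase < 0 or n_decrease < 0 or n_increase + n_decrease > n_total:
        raise ValueError("inconsistent direction counts")
    n_changed = n_increase + n_decrease
    if n_changed == 0:
        return 1.0
    rng = as_generator(seed)
    draws = rng.binomial(n_changed, 0.5, size=n_mc)
    observed = abs(n_increase - n_changed / 2.0)
    extreme = np.abs(draws - n_changed / 2.0) >= observed - 1e-12
    return float((1.0 + extreme.sum()) / (1.0 + n_mc))


@dataclass
class InstabilityResult:
    r2: float
    p_value: float
    slope: float
    degenerate: bool


def instability_control(rate_changes, accuracy_changes) -> InstabilityResult:
    """Correlate per-unit firing-rate change with decoding-accuracy change.

    A large r-squared would indicate that apparent coding changes merely
    track recording instability.  Zero-variance input is flagged degenerate.
    """
    x = np.asarray(rate_changes, dtype=float)
    y = np.asarray(accuracy_changes, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("at least three paired observations are required")
    if np.std(x) == 0 or np.std(y) == 0:
        return InstabilityResult(r2=float("nan"), p_value=float("nan"),
                                 slope=float("nan"), degenerate=True)
    res = stats.pearsonr(x, y)
    slope = float(np.polyfit(x, y, 1)[0])
    return InstabilityResult(r2=float(res.statistic**2), p_value=float(res.pvalue),
                             slope=slope, degenerate=False)
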