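"""Single-trial decoding from instantaneous-rate features.

Spike trains are converted to instantaneous firing rates by convolution with
a unit-area Gaussian kernel evaluated at the PSTH/PETH bin centers; a
two-class pooled-covariance linear discriminant with leave-one-out
validation then measures how well neural firing separates two conditions
(chance = 50% for balanced pairs).

The discriminant uses equal class priors and a fixed shrinkage of the pooled
covariance toward its diagonal (coefficient 0.1 by default) so that the
features >> trials regime stays well conditioned; discriminant-score ties
are broken toward the lexicographically first class label.  Leave-one-out
refits are computed exactly, via rank-one downdates of the pooled scatter,
which is algebraically identical to refitting on each training fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from pairedstim._rng import as_generator
from pairedstim.inference import benjamini_hochberg

#: Gaussian kernel truncated at +-4 sigma for rate evaluation
_KERNEL_SUPPORT = 4.0


@dataclass
class RateFeatureMatrix:
    """Trials x time-samples instantaneous-rate features."""

    values: np.ndarray  # (n_trials, n_bins), spikes/s
    labels: np.ndarray  # per-trial class label
    bin_centers: np.ndarray  # seconds relative to the alignment event
    kernel_width: float  # Gaussian sigma, seconds
    window: tuple[float, float]
    bin_width: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError("one label per trial is required")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]


@dataclass
class DecodingResult:
    """Leave-one-out decoding outcome for one class pair."""

    accuracy: float
    per_trial_correct: np.ndarray
    predicted: np.ndarray
    classes: tuple
    kernel_width: float | None = None


@dataclass
class AccuracyChangeTest:
    """Per-unit Monte Carlo test for a before/after accuracy change."""

    observed_delta: float  # accuracy_after - accuracy_before
    p_value: float
    direction: str  # {increase, decrease, no change}
    n_mc: int
    accuracy_before: float
    accuracy_after: float


def rate_features(
    trial_spikes: Sequence[np.ndarray],
    labels: Sequence,
    *,
    window: tuple[float, float],
    bin_width: float,
    kernel_width: float,
) -> RateFeatureMatrix:
    """Gaussian-kernel instantaneous rate per trial, sampled at bin centers.

    rate(t) = sum_spikes G(t - t_spike; sigma) with G the unit-area Gaussian,
    so a row integrates to approximately the trial's spike count (exactly,
    for spikes far from the window edges; no edge padding is applied).
    Trials without spikes yield all-zero rows.
    """
    if kernel_width <= 0:
        raise ValueError("kernel_width must be positive")
    n_bins = round((window[1] - window[0]) / bin_width)
    centers = window[0] + bin_width * (np.arange(n_bins) + 0.5)
    norm = 1.0 / (kernel_width * math.sqrt(2.0 * math.pi))
    support = _KERNEL_SUPPORT * kernel_width
    rows = np.zeros((len(trial_spikes), n_bins))
    for i, spikes in enumerate(trial_spikes):
        s = np.asarray(spikes, dtype=float)
        if s.size == 0:
            continue
        diff = centers[None, :] - s[:, None]
        contrib = np.where(
            np.abs(diff) <= support,
            np.exp(-0.5 * (diff / kernel_width) ** 2),
            0.0,
        )
        rows[i] = norm * contrib.sum(axis=0)
    return RateFeatureMatrix(
        values=rows,
        labels=np.asarray(labels),
        bin_centers=centers,
        kernel_width=kernel_width,
        window=window,
        bin_width=bin_width,
    )


def _loo_predict(X: np.ndarray, y01: np.ndarray, shrinkage: float,
                 ridge: float, chunk: int = 256) -> np.ndarray:
    """Exact leave-one-out predictions of the shrunk pooled-covariance LDA.

    For the fold dropping trial i of class c, the pooled scatter downdates by
    the rank-one term (n_c/(n_c-1)) u u^T with u = x_i - mu_c, and the
    diagonal shrinkage target downdates consistently; the per-fold system is
    solved batched.  Ties (discriminant score exactly 0) go to class 0.
    """
    n, d = X.shape
    n0 = int(np.sum(y01 == 0))
    n1 = n - n0
    if n0 < 2 or n1 < 2:
        raise ValueError("each class needs at least two trials")
    mu0 = X[y01 == 0].mean(axis=0)
    mu1 = X[y01 == 1].mean(axis=0)
    Xc = X - np.where(y01[:, None] == 0, mu0, mu1)
    G = Xc.T @ Xc
    dof = n - 3  # pooled dof after removing one trial
    lam = shrinkage
    base = ((1.0 - lam) * G + lam * np.diag(np.diag(G))) / dof
    ridge_eff = ridge * (np.trace(base) / d + 1.0)
    base = base + ridge_eff * np.eye(d)

    mu_own = np.where(y01[:, None] == 0, mu0, mu1)
    U = X - mu_own
    n_own = np.where(y01 == 0, n0, n1).astype(float)
    coef = (n_own / (n_own - 1.0)) / dof

    # fold-wise class means and midpoints
    mu0_f = np.where(y01[:, None] == 0, mu0 - U / (n0 - 1.0), mu0)
    mu1_f = np.where(y01[:, None] == 1, mu1 - U / (n1 - 1.0), mu1)
    delta = mu1_f - mu0_f
    mid = 0.5 * (mu0_f + mu1_f)

    preds = np.empty(n, dtype=int)
    diag_idx = np.arange(d)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        u = U[lo:hi]
        c = coef[lo:hi]
        S = np.broadcast_to(base, (hi - lo, d, d)).copy()
        S -= (c[:, None, None] * (1.0 - lam)) * (u[:, :, None] * u[:, None, :])
        S[:, diag_idx, diag_idx] -= c[:, None] * lam * u**2
        try:
            w = np.linalg.solve(S, delta[lo:hi][:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:  # fall back fold-by-fold
            w = np.stack(
                [np.linalg.lstsq(S[k], delta[lo + k], rcond=None)[0]
                 for k in range(hi - lo)]
            )
        score = np.einsum("ij,ij->i", w, X[lo:hi] - mid[lo:hi])
        preds[lo:hi] = (score > 0.0).astype(int)
    return preds


def loo_lda(
    features: RateFeatureMatrix | None = None,
    *,
    values: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    shrinkage: float = 0.1,
    ridge: float = 1e-8,
) -> DecodingResult:
    """Leave-one-out two-class linear discriminant decoding.

    Accepts either a :class:`RateFeatureMatrix` or raw ``values``/``labels``.
    Deterministic given the features: no internal randomness.
    """
    if features is not None:
        values = features.values
        labels = features.labels
        kernel_width = features.kernel_width
    else:
        kernel_width = None
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError(f"exactly two classes are required, got {classes}")
    y01 = (labels == classes[1]).astype(int)
    preds = _loo_predict(values, y01, shrinkage, ridge)
    correct = preds == y01
    return DecodingResult(
        accuracy=float(np.mean(correct)),
        per_trial_correct=correct,
        predicted=np.asarray(classes, dtype=object)[preds],
        classes=tuple(classes),
        kernel_width=kernel_width,
    )


def kernel_sweep(
    trial_spikes: Sequence[np.ndarray],
    labels: Sequence,
    widths: Sequence[float],
    *,
    window: tuple[float, float],
    bin_width: float,
    shrinkage: float = 0.1,
) -> pd.DataFrame:
    """LOO-LDA accuracy as a function of the Gaussian kernel width."""
    rows = []
    for width in widths:
        feats = rate_features(
            trial_spikes, labels, window=window, bin_width=bin_width, kernel_width=width
        )
        res = loo_lda(feats, shrinkage=shrinkage)
        rows.append({"kernel_width": width, "accuracy": res.accuracy})
    return pd.DataFrame(rows)


def accuracy_change_mc_test(
    features_before: RateFeatureMatrix,
    features_after: RateFeatureMatrix,
    *,
    n_mc: int = 1000,
    seed=0,
    shrinkage: float = 0.1,
) -> AccuracyChangeTest:
    """Monte Carlo test of a per-unit change in LOO-LDA accuracy.

    The null distribution pools trials across the two epochs and, within
    each class, randomly reassigns epoch labels (respecting both the epoch
    group sizes and the class counts per epoch); the accuracy difference is
    recomputed per permutation and the two-sided p-value taken from the
    permutation distribution with the add-one estimator.
    """
    classes_b = sorted(set(features_before.labels.tolist()))
    classes_a = sorted(set(features_after.labels.tolist()))
    if classes_b != classes_a:
        raise ValueError("before/after must compare the same class pair")
    rng = as_generator(seed)

    acc_before = loo_lda(features_before, shrinkage=shrinkage).accuracy
    acc_after = loo_lda(features_after, shrinkage=shrinkage).accuracy
    observed = acc_after - acc_before

    null = np.empty(n_mc)
    for k in range(n_mc):
        vals_b, labs_b, vals_a, labs_a = [], [], [], []
        for cls in classes_b:
            xb = features_before.values[features_before.labels == cls]
            xa = features_after.values[features_after.labels == cls]
            pooled = np.concatenate([xb, xa])
            perm = rng.permutation(len(pooled))
            vals_b.append(pooled[perm[: len(xb)]])
            vals_a.append(pooled[perm[len(xb):]])
            labs_b.extend([cls] * len(xb))
            labs_a.extend([cls] * len(xa))
        rb = loo_lda(values=np.concatenate(vals_b), labels=np.asarray(labs_b),
                     shrinkage=shrinkage)
        ra = loo_lda(values=np.concatenate(vals_a), labels=np.asarray(labs_a),
                     shrinkage=shrinkage)
        null[k] = ra.accuracy - rb.accuracy

    p = (1.0 + np.sum(np.abs(null) >= abs(observed) - 1e-12)) / (1.0 + n_mc)
    if observed > 0:
        direction = "increase"
    elif observed < 0:
        direction = "decrease"
    else:
        direction = "no change"
    return AccuracyChangeTest(
        observed_delta=float(observed),
        p_value=float(p),
        direction=direction,
        n_mc=n_mc,
        accuracy_before=acc_before,
        accuracy_after=acc_after,
    )


def population_accuracy_tests(
    results: pd.DataFrame,
    *,
    q: float = 0.05,
) -> pd.DataFrame:
    """Population-level before/after accuracy comparisons.

    ``results`` needs columns ``comparison``, ``accuracy_before`` and
    ``accuracy_after`` (one row per unit).  Per comparison, a Wilcoxon
    signed-rank test on the paired accuracies plus the proportions of units
    increasing / decreasing / unchanged; raw p-values are Benjamini-Hochberg
    corrected across comparisons.
    """
    rows = []
    for comparison, grp in results.groupby("comparison", sort=True):
        before = grp["accuracy_before"].to_numpy(dtype=float)
        after = grp["accuracy_after"].to_numpy(dtype=float)
        if len(before) < 5:
            raise ValueError("at least five before/after pairs are required")
        diffs = after - before
        if np.all(diffs == 0):
            import warnings

            warnings.warn(f"all pairs tied for comparison {comparison!r}", stacklevel=2)
            p = 1.0
        else:
            p = float(stats.wilcoxon(before, after).pvalue)
        rows.append(
            {
                "comparison": comparison,
                "n_units": len(grp),
                "mean_before": float(np.mean(before)),
                "mean_after": float(np.mean(after)),
                "prop_increase": float(np.mean(diffs > 0)),
                "prop_decrease": float(np.mean(diffs < 0)),
                "prop_no_change": float(np.mean(diffs == 0)),
                "p_raw": p,
            }
        )
    table = pd.DataFrame(rows)
    family = benjamini_hochberg(table["p_raw"].to_numpy(), q=q,
                                labels=table["comparison"].tolist())
    table["p_bh"] = family.adjusted
    table["significant"] = family.rejected
    return table
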