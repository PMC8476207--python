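"""Behavioral task scoring and condition comparisons.

A trial succeeds when the instructed digit abducts beyond its minimal-motion
threshold while the noninstructed digit stays below its maximal-motion
threshold (thumb-instructed: thumb > 7 deg and index < 11 deg;
index-instructed: index > 8 deg and thumb < 17 deg; inequalities strict).
Per epoch, performance A = c/(e+c) and speed s = c/t (correct trials per
minute over the epoch duration t).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from pairedstim.inference import benjamini_hochberg
from pairedstim.synthetic import INSTRUCTED_MIN_DEG, NONINSTRUCTED_MAX_DEG, TrialRecord


@dataclass
class BehaviorMetrics:
    """Per-epoch behavioral summary (c, e, A, s) with per-digit splits."""

    c: int  # correct trials
    e: int  # error trials
    A: float | None  # performance c/(e+c); None when no trials
    s: float  # speed, correct trials per minute
    t: float  # epoch duration, minutes
    per_digit: dict = field(default_factory=dict)
    max_displacement: pd.DataFrame | None = None


def classify_trial(trial: TrialRecord) -> bool:
    """Apply the success thresholds to one trial's lever traces."""
    if trial.thumb_trace is None or trial.index_trace is None or len(trial.thumb_trace) == 0:
        raise ValueError("trial traces are missing")
    peaks = {"thumb": float(np.max(trial.thumb_trace)),
             "index": float(np.max(trial.index_trace))}
    instructed = trial.instructed
    noninstructed = "index" if instructed == "thumb" else "thumb"
    return (
        peaks[instructed] > INSTRUCTED_MIN_DEG[instructed]
        and peaks[noninstructed] < NONINSTRUCTED_MAX_DEG[instructed]
    )


def score_epoch(trials: list[TrialRecord], duration_min: float) -> BehaviorMetrics:
    """Score one task epoch; also reports per-digit splits and per-trial
    maximum lever displacements."""
    if duration_min <= 0:
        raise ValueError("duration must be positive")

    def summarize(subset, t_min):
        c = sum(1 for t in subset if classify_trial(t))
        e = len(subset) - c
        a = c / (e + c) if (e + c) > 0 else None
        if a is None:
            warnings.warn("no trials: performance A undefined", stacklevel=3)
        return c, e, a, c / t_min

    c, e, a, s = summarize(trials, duration_min)
    per_digit = {}
    for digit in ("thumb", "index"):
        subset = [t for t in trials if t.instructed == digit]
        if subset:
            dc, de, da, ds = summarize(subset, duration_min)
            per_digit[digit] = {"c": dc, "e": de, "A": da, "s": ds}
    disp = pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in trials],
            "instructed": [t.instructed for t in trials],
            "thumb_max_deg": [float(np.max(t.thumb_trace)) for t in trials],
            "index_max_deg": [float(np.max(t.index_trace)) for t in trials],
        }
    )
    return BehaviorMetrics(c=c, e=e, A=a, s=s, t=duration_min,
                           per_digit=per_digit, max_displacement=disp)


def compare_conditions(deltas: pd.DataFrame, measures=("delta_A", "delta_s", "delta_e"),
                       q: float = 0.05) -> dict:
    """Two-way ANOVA (MONKEY x STIMULATION) plus post hoc t tests on
    per-session before-to-after deltas.

    ``deltas`` needs columns ``monkey``, ``condition`` plus the measure
    columns; deltas are after - before, so positive values mean improvement.
    Post hoc one-sample (each condition vs 0) and two-sample (synchronous vs
    asynchronous) t tests are Benjamini-Hochberg corrected as one family
    across all measures.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    results: dict = {"anova": {}, "posthoc": None}
    posthoc_rows = []
    for measure in measures:
        if measure not in deltas.columns:
            continue
        df = deltas[["monkey", "condition", measure]].rename(columns={measure: "y"})
        if np.allclose(df["y"].to_numpy(), df["y"].to_numpy()[0]):
            # constant response: no variance to partition
            anova = pd.DataFrame(
                {"F": [0.0, 0.0, 0.0], "PR(>F)": [1.0, 1.0, 1.0]},
                index=["C(monkey)", "C(condition)", "C(monkey):C(condition)"],
            )
            anova.attrs["degenerate"] = True
        else:
            cell_counts = df.groupby(["monkey", "condition"]).size()
            full_design = len(cell_counts) == df["monkey"].nunique() * df["condition"].nunique()
            formula = (
                "y ~ C(monkey) * C(condition)" if full_design else "y ~ C(monkey) + C(condition)"
            )
            if not full_design:
                warnings.warn("empty design cell: interaction omitted", stacklevel=2)
            model = smf.ols(formula, data=df).fit()
            anova = sm.stats.anova_lm(model, typ=2)
        results["anova"][measure] = anova

        for condition, grp in df.groupby("condition", sort=True):
            y = grp["y"].to_numpy()
            if np.std(y) == 0:
                p = 1.0 if np.allclose(y, 0) else 0.0
            else:
                p = float(stats.ttest_1samp(y, 0.0).pvalue)
            posthoc_rows.append(
                {"measure": measure, "test": f"{condition} vs 0",
                 "estimate": float(np.mean(y)), "p_raw": p}
            )
        groups = {c: g["y"].to_numpy() for c, g in df.groupby("condition", sort=True)}
        if len(groups) == 2:
            (ca, ya), (cb, yb) = sorted(groups.items())
            if np.std(ya) == 0 and np.std(yb) == 0:
                p = 1.0 if np.mean(ya) == np.mean(yb) else 0.0
            else:
                p = float(stats.ttest_ind(ya, yb).pvalue)
            posthoc_rows.append(
                {"measure": measure, "test": f"{ca} vs {cb}",
                 "estimate": float(np.mean(ya) - np.mean(yb)), "p_raw": p}
            )

    posthoc = pd.DataFrame(posthoc_rows)
    if len(posthoc):
        family = benjamini_hochberg(posthoc["p_raw"].to_numpy(), q=q)
        posthoc["p_bh"] = family.adjusted
        posthoc["significant"] = family.rejected
    results["posthoc"] = posthoc
    return results
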