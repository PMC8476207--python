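"""Bin-wise Poisson Z statistics for before/after comparisons.

Counts in a PSTH/PETH bin are modeled as Poisson, so the variance of a rate
estimate equals its mean.  For stimulus-aligned histograms the comparison is
baseline-corrected:

    Z = [(N_aft/m_aft - B_aft/(m_aft n_aft)) - (N_bef/m_bef - B_bef/(m_bef n_bef))]
        / sqrt(N_aft/m_aft^2 + B_aft/(m_aft^2 n_aft^2)
               + N_bef/m_bef^2 + B_bef/(m_bef^2 n_bef^2))

with N the bin count, m the trial count, B the total count over the n
baseline bins.  Task-aligned histograms have no clear baseline period:

    Z = (N_aft/m_aft - N_bef/m_bef) / sqrt(N_aft/m_aft^2 + N_bef/m_bef^2)

Under the null hypothesis of an unchanged response, Z is approximately
standard normal per bin.  The population average over N units,
Zbar = (1/sqrt(N)) sum_i Z_i, and the contrast between two conditions,
(Z_a - Z_b)/sqrt(2), are normalized so they stay standard normal under the
null; bins with |Z| > 1.96 are flagged as significant at the two-sided 95%
level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from pairedstim.histograms import EventHistogram

DEFAULT_CI = 1.96


@dataclass
class ZSeries:
    """Per-bin Z values with significance shading."""

    z: np.ndarray
    window: tuple[float, float]
    bin_width: float
    blanked: np.ndarray  # bool; blanked bins carry z = 0 and no significance
    degenerate: np.ndarray  # bool; zero-denominator bins, z forced to 0
    kind: str  # {stimulus, task, population, difference}
    ci: float = DEFAULT_CI
    sig_up: np.ndarray = field(default=None)
    sig_down: np.ndarray = field(default=None)

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.blanked = np.asarray(self.blanked, dtype=bool)
        self.degenerate = np.asarray(self.degenerate, dtype=bool)
        valid = ~self.blanked
        if self.sig_up is None:
            self.sig_up = (self.z > self.ci) & valid
        if self.sig_down is None:
            self.sig_down = (self.z < -self.ci) & valid

    @property
    def bin_starts(self) -> np.ndarray:
        return self.window[0] + self.bin_width * np.arange(len(self.z))

    def same_grid(self, other: "ZSeries") -> bool:
        return (
            len(self.z) == len(other.z)
            and np.isclose(self.window[0], other.window[0])
            and np.isclose(self.bin_width, other.bin_width)
            and bool(np.array_equal(self.blanked, other.blanked))
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start_ms": np.round(self.bin_starts * 1000.0, 6),
                "z": self.z,
                "sig_up": self.sig_up,
                "sig_down": self.sig_down,
                "blanked": self.blanked,
            }
        )


def default_baseline_bins(hist: EventHistogram) -> np.ndarray:
    """All unblanked pre-stimulus bins (bins ending at or before 0)."""
    ends = hist.bin_starts + hist.bin_width
    return np.flatnonzero((ends <= 1e-12) & ~hist.blank_mask)


def _check_grids(a: EventHistogram, b: EventHistogram) -> None:
    if not a.same_grid(b):
        raise ValueError("histograms must share window, bin width and blanking")


def _finalize(num, den, blanked, window, bin_width, kind, ci) -> ZSeries:
    degenerate = (den == 0) & ~blanked
    safe_den = np.where(den == 0, 1.0, den)
    z = np.where(blanked | degenerate, 0.0, num / safe_den)
    return ZSeries(
        z=z,
        window=window,
        bin_width=bin_width,
        blanked=blanked,
        degenerate=degenerate,
        kind=kind,
        ci=ci,
    )


def z_stimulus(
    before: EventHistogram,
    after: EventHistogram,
    baseline_bins: np.ndarray | None = None,
    ci: float = DEFAULT_CI,
) -> ZSeries:
    """Baseline-corrected per-bin Z for stimulus-aligned histograms.

    ``baseline_bins`` defaults to all unblanked pre-stimulus bins of the
    shared grid.  Bins where all four counts are zero get Z = 0 and a
    degeneracy flag.
    """
    _check_grids(before, after)
    if baseline_bins is None:
        baseline_bins = default_baseline_bins(before)
    baseline_bins = np.asarray(baseline_bins, dtype=int)
    if baseline_bins.size == 0:
        raise ValueError("baseline_bins must be non-empty")
    if np.any(before.blank_mask[baseline_bins]):
        raise ValueError("baseline_bins must all be unblanked")

    n_base = baseline_bins.size
    m_bef, m_aft = before.n_trials, after.n_trials
    b_bef = float(before.counts[baseline_bins].sum())
    b_aft = float(after.counts[baseline_bins].sum())
    n_bef = before.counts.astype(float)
    n_aft = after.counts.astype(float)

    num = (n_aft / m_aft - b_aft / (m_aft * n_base)) - (
        n_bef / m_bef - b_bef / (m_bef * n_base)
    )
    var = (
        n_aft / m_aft**2
        + b_aft / (m_aft**2 * n_base**2)
        + n_bef / m_bef**2
        + b_bef / (m_bef**2 * n_base**2)
    )
    return _finalize(num, np.sqrt(var), before.blank_mask, before.window,
                     before.bin_width, "stimulus", ci)


def z_task(before: EventHistogram, after: EventHistogram, ci: float = DEFAULT_CI) -> ZSeries:
    """Baseline-free per-bin Z for task-aligned histograms."""
    _check_grids(before, after)
    m_bef, m_aft = before.n_trials, after.n_trials
    n_bef = before.counts.astype(float)
    n_aft = after.counts.astype(float)
    num = n_aft / m_aft - n_bef / m_bef
    var = n_aft / m_aft**2 + n_bef / m_bef**2
    return _finalize(num, np.sqrt(var), before.blank_mask, before.window,
                     before.bin_width, "task", ci)


def z_population(series: Sequence[ZSeries], ci: float = DEFAULT_CI) -> ZSeries:
    """Variance-preserving population average: Zbar = (1/sqrt(N)) sum_i Z_i."""
    if len(series) == 0:
        raise ValueError("at least one ZSeries is required")
    first = series[0]
    for s in series[1:]:
        if not first.same_grid(s):
            raise ValueError("all ZSeries must share the same grid")
    stack = np.stack([s.z for s in series])
    z = stack.sum(axis=0) / np.sqrt(len(series))
    degenerate = np.logical_and.reduce([s.degenerate for s in series])
    return ZSeries(
        z=np.where(first.blanked, 0.0, z),
        window=first.window,
        bin_width=first.bin_width,
        blanked=first.blanked.copy(),
        degenerate=degenerate,
        kind="population",
        ci=ci,
    )


def z_difference(a: ZSeries, b: ZSeries, ci: float = DEFAULT_CI) -> ZSeries:
    """Renormalized condition contrast (a - b) / sqrt(2)."""
    if not a.same_grid(b):
        raise ValueError("ZSeries must share the same grid")
    z = (a.z - b.z) / np.sqrt(2.0)
    return ZSeries(
        z=np.where(a.blanked, 0.0, z),
        window=a.window,
        bin_width=a.bin_width,
        blanked=a.blanked.copy(),
        degenerate=a.degenerate & b.degenerate,
        kind="difference",
        ci=ci,
    )


def plot_zseries(zs: ZSeries, ax=None, title: str = ""):
    """Shaded Z panel: significant bins above/below the confidence lines."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 2.5))
    x = zs.bin_starts * 1000.0
    ax.plot(x, zs.z, color="k", lw=0.8, drawstyle="steps-post")
    ax.fill_between(x, zs.ci, zs.z, where=zs.sig_up, step="post", color="orange")
    ax.fill_between(x, -zs.ci, zs.z, where=zs.sig_down, step="post", color="cyan")
    ax.axhline(zs.ci, color="gray", lw=0.6)
    ax.axhline(-zs.ci, color="gray", lw=0.6)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("Z")
    if title:
        ax.set_title(title)
    return ax
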