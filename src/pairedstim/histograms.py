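"""Peristimulus / perievent time histograms and the ISI-shuffle test.

Stimulus-aligned PSTHs use 1-ms half-open bins on [-20, +100) ms with the
bins covering 0..6 ms post-stimulus blanked (stimulus artifact) plus the bin
containing -10 ms (relay-switching artifact).  Task-aligned PETHs use 10-ms
bins on [-500, +200) ms around the completion of successful trials, with no
blanking.

The interspike-interval shuffle test asks whether a unit's PETH modulation
(max - min bin rate) exceeds what trial-wise ISI shuffling produces: each
trial's ISI sequence is permuted (first-spike latency and spike count
preserved), the PETH rebuilt, and the observed modulation declared
significant when it exceeds more than 95% of the shuffled modulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from pairedstim._rng import as_generator

PSTH_WINDOW = (-0.020, 0.100)
PSTH_BIN_WIDTH = 0.001
PETH_WINDOW = (-0.500, 0.200)
PETH_BIN_WIDTH = 0.010

#: stimulus-artifact blanking interval: bins with a start in [0 ms, 6 ms]
#: (seven 1-ms bins, covering "0 ms before to 6 ms after" the stimulus)
PSTH_BLANK_POST = (0.0, 0.007)
#: relay switching happens 10 ms before the stimulus
RELAY_TIME = -0.010


def _n_bins(window: tuple[float, float], bin_width: float) -> int:
    n = (window[1] - window[0]) / bin_width
    n_int = round(n)
    if abs(n - n_int) > 1e-9:
        raise ValueError("window length must be an exact multiple of bin_width")
    return n_int


@dataclass
class EventHistogram:
    """Binned spike counts aligned to an event."""

    counts: np.ndarray  # int, per bin
    n_trials: int  # m in the Z formulas
    window: tuple[float, float]  # seconds relative to the alignment event
    bin_width: float  # seconds
    blank_mask: np.ndarray  # bool, True where the bin was blanked
    alignment: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.blank_mask = np.asarray(self.blank_mask, dtype=bool)
        if self.counts.shape != self.blank_mask.shape:
            raise ValueError("counts and blank_mask must have equal length")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.counts[self.blank_mask] != 0):
            raise ValueError("blanked bins must carry zero counts")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def bin_starts(self) -> np.ndarray:
        return self.window[0] + self.bin_width * np.arange(self.n_bins)

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_starts + self.bin_width / 2.0

    def rates(self) -> np.ndarray:
        """Mean firing rate per bin in spikes/s: count / (m * bin_width)."""
        return self.counts / (self.n_trials * self.bin_width)

    def same_grid(self, other: "EventHistogram") -> bool:
        return (
            self.n_bins == other.n_bins
            and np.isclose(self.window[0], other.window[0])
            and np.isclose(self.bin_width, other.bin_width)
            and bool(np.array_equal(self.blank_mask, other.blank_mask))
        )


def psth_blank_mask(
    window: tuple[float, float] = PSTH_WINDOW,
    bin_width: float = PSTH_BIN_WIDTH,
    blank_post: tuple[float, float] = PSTH_BLANK_POST,
    relay_time: float | None = RELAY_TIME,
) -> np.ndarray:
    """Blanking mask for a stimulus-aligned grid."""
    n = _n_bins(window, bin_width)
    starts = window[0] + bin_width * np.arange(n)
    eps = 1e-9
    mask = (starts >= blank_post[0] - eps) & (starts < blank_post[1] - eps)
    if relay_time is not None and window[0] - eps <= relay_time < window[1]:
        mask[int(np.floor((relay_time - window[0]) / bin_width + eps))] = True
    return mask


def _histogram(rel_times: np.ndarray, window, bin_width) -> np.ndarray:
    n = _n_bins(window, bin_width)
    idx = np.floor((rel_times - window[0]) / bin_width).astype(int)
    ok = (idx >= 0) & (idx < n)
    return np.bincount(idx[ok], minlength=n)


def per_trial_spikes(
    spike_times: np.ndarray,
    align_times: np.ndarray,
    window: tuple[float, float],
) -> list[np.ndarray]:
    """Spike times relative to each alignment event, clipped to the window."""
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    out = []
    for t in np.asarray(align_times, dtype=float):
        lo = np.searchsorted(spike_times, t + window[0], side="left")
        hi = np.searchsorted(spike_times, t + window[1], side="left")
        out.append(spike_times[lo:hi] - t)
    return out


def build_psth(
    spike_times: np.ndarray,
    event_times: np.ndarray,
    *,
    window: tuple[float, float] = PSTH_WINDOW,
    bin_width: float = PSTH_BIN_WIDTH,
    blank: bool = True,
    alignment: str = "stimulus",
) -> EventHistogram:
    """Stimulus-aligned histogram with artifact blanking.

    Bins are half-open ``[t, t + bin_width)``; spikes outside every window
    are ignored.
    """
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size == 0:
        raise ValueError("at least one alignment event is required")
    rel = np.concatenate(per_trial_spikes(spike_times, event_times, window)) if len(
        event_times
    ) else np.empty(0)
    counts = _histogram(rel, window, bin_width)
    if blank:
        mask = psth_blank_mask(window, bin_width)
        counts = counts.copy()
        counts[mask] = 0
    else:
        mask = np.zeros(len(counts), dtype=bool)
    return EventHistogram(
        counts=counts,
        n_trials=len(event_times),
        window=window,
        bin_width=bin_width,
        blank_mask=mask,
        alignment=alignment,
    )


def build_peth(
    spike_times: np.ndarray,
    completion_times: np.ndarray,
    *,
    window: tuple[float, float] = PETH_WINDOW,
    bin_width: float = PETH_BIN_WIDTH,
    alignment: str = "trial_completion",
) -> EventHistogram:
    """Histogram aligned to the completion of successful trials (no blanking)."""
    completion_times = np.asarray(completion_times, dtype=float)
    if completion_times.size == 0:
        raise ValueError("at least one qualifying trial is required")
    rel = np.concatenate(per_trial_spikes(spike_times, completion_times, window))
    counts = _histogram(rel, window, bin_width)
    return EventHistogram(
        counts=counts,
        n_trials=len(completion_times),
        window=window,
        bin_width=bin_width,
        blank_mask=np.zeros(len(counts), dtype=bool),
        alignment=alignment,
    )


@dataclass
class ModulationTest:
    """Result of the ISI-shuffle modulation test."""

    peak_modulation: float  # spikes/s, max - min bin rate
    n_shuffles: int
    exceedance_rank: float  # fraction of shuffles strictly below observed
    significant: bool  # exceedance_rank > 0.95
    shuffled_modulations: np.ndarray = field(repr=False, default=None)
    observed_counts: np.ndarray = field(repr=False, default=None)
    shuffled_counts: np.ndarray = field(repr=False, default=None)  # kept on request


def _peak_modulation(counts: np.ndarray, n_trials: int, bin_width: float,
                     unblanked: np.ndarray) -> float:
    rates = counts[unblanked] / (n_trials * bin_width)
    return float(rates.max() - rates.min())


def shuffle_modulation_test(
    trial_spikes: Sequence[np.ndarray],
    *,
    window: tuple[float, float] = PETH_WINDOW,
    bin_width: float = PETH_BIN_WIDTH,
    n_shuffles: int = 1000,
    seed=0,
    blank_mask: np.ndarray | None = None,
    keep_counts: bool = False,
) -> ModulationTest:
    """ISI-shuffle significance test for event-locked modulation.

    ``trial_spikes`` holds, per trial, spike times relative to the alignment
    event (within ``window``).  Each shuffle permutes every trial's ISI
    sequence while preserving the first spike's latency and the per-trial
    spike count; trials with <= 1 spike are carried unchanged.  Ties between
    the observed and a shuffled modulation count against significance.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be at least 100")
    rng = as_generator(seed)
    n_bins = _n_bins(window, bin_width)
    unblanked = (
        ~np.asarray(blank_mask, dtype=bool)
        if blank_mask is not None
        else np.ones(n_bins, dtype=bool)
    )
    m = len(trial_spikes)
    if m == 0:
        raise ValueError("at least one trial is required")

    observed = np.zeros(n_bins, dtype=int)
    shuffled = np.zeros((n_shuffles, n_bins), dtype=np.int64)
    flat_len = n_shuffles * n_bins
    for spikes in trial_spikes:
        s = np.sort(np.asarray(spikes, dtype=float))
        observed += _histogram(s, window, bin_width)
        if s.size == 0:
            continue
        if s.size == 1:
            idx = int((s[0] - window[0]) / bin_width)
            if 0 <= idx < n_bins:
                shuffled[:, idx] += 1
            continue
        isis = np.diff(s)
        # one random permutation of the ISIs per shuffle, via argsort of
        # uniform keys (vectorized Fisher-Yates equivalent)
        order = np.argsort(rng.random((n_shuffles, isis.size)), axis=1)
        perm = np.take_along_axis(np.broadcast_to(isis, order.shape), order, axis=1)
        times = s[0] + np.concatenate(
            [np.zeros((n_shuffles, 1)), np.cumsum(perm, axis=1)], axis=1
        )
        idx = np.floor((times - window[0]) / bin_width).astype(int)
        np.clip(idx, 0, n_bins - 1, out=idx)  # guards float round-off only
        flat = (np.arange(n_shuffles)[:, None] * n_bins + idx).ravel()
        shuffled += np.bincount(flat, minlength=flat_len).reshape(n_shuffles, n_bins)

    if np.any(observed[~unblanked] != 0):
        observed = observed.copy()
        observed[~unblanked] = 0
    obs_mod = _peak_modulation(observed, m, bin_width, unblanked)
    r = shuffled[:, unblanked] / (m * bin_width)
    shuffled_mods = r.max(axis=1) - r.min(axis=1)
    rank = float(np.mean(shuffled_mods < obs_mod))
    return ModulationTest(
        peak_modulation=obs_mod,
        n_shuffles=n_shuffles,
        exceedance_rank=rank,
        significant=bool(rank > 0.95),
        shuffled_modulations=shuffled_mods,
        observed_counts=observed,
        shuffled_counts=shuffled if keep_counts else None,
    )
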