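"""Threshold-based spike event detection from a raw voltage trace.

The threshold follows the robust median rule

    theta = 5 * median(|x|) / 0.6745

where the median is taken over the entire available recording; for Gaussian
noise median(|x|) = 0.6745 * sigma, so theta estimates five noise standard
deviations independently of spike contamination of the tails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: median of |N(0, 1)|
_MAD_GAUSS = 0.6745


@dataclass
class DetectionResult:
    threshold: float
    event_times: np.ndarray  # seconds
    polarity: str  # {"positive", "negative", "both"}
    fs: float


def compute_threshold(trace: np.ndarray) -> float:
    """Robust amplitude threshold ``5 * median(|x|) / 0.6745``.

    An all-zero trace yields theta = 0, flagged with a warning (degenerate:
    every sample then crosses threshold).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("trace must be non-empty")
    theta = 5.0 * float(np.median(np.abs(trace))) / _MAD_GAUSS
    if theta == 0.0:
        warnings.warn("degenerate trace: threshold is 0", stacklevel=2)
    return theta


def detect_events(
    trace: np.ndarray,
    threshold: float,
    fs: float = 25000.0,
    lockout: float = 0.001,
    polarity: str = "both",
) -> DetectionResult:
    """Times of first samples of excursions beyond the threshold.

    ``polarity`` selects crossings of +theta, -theta, or either (``both``,
    the default, matching detection at +-theta).  Crossings within
    ``lockout`` seconds of an accepted event are suppressed; the default
    1 ms lockout prevents one waveform from being counted twice.
    """
    trace = np.asarray(trace, dtype=float)
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if lockout < 1.0 / fs:
        raise ValueError("lockout must be at least one sampling period")
    if polarity == "positive":
        above = trace >= threshold
    elif polarity == "negative":
        above = trace <= -threshold
    elif polarity == "both":
        above = np.abs(trace) >= threshold
    else:
        raise ValueError(f"unknown polarity {polarity!r}")

    onsets = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))
    lock_samples = int(round(lockout * fs))
    kept = []
    last = -lock_samples - 1
    for i in onsets:
        if i - last >= lock_samples:
            kept.append(i)
            last = i
    return DetectionResult(
        threshold=float(threshold),
        event_times=np.asarray(kept, dtype=float) / fs,
        polarity=polarity,
        fs=fs,
    )
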