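"""Synthetic session generator for the paired-stimulation experiment.

Emulates the six-epoch design: a behavioral assessment and three rounds of
individual nerve stimulation (EDC, median, ulnar) bracketing ~1 h of paired
median/ulnar stimulation, delivered either synchronously (both nerves at the
same instant) or asynchronously (the second nerve halfway through each
interstimulus interval).

Spikes are drawn from an inhomogeneous Poisson process whose rate is a
baseline plus stimulus-locked Gaussian transients per electrode and
task-locked profiles per trial type, with multiplicative "plasticity"
effects applied in the post-intervention epochs.  All randomness flows from
one seed through named substreams.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from pairedstim._rng import as_generator, substream

ELECTRODES = ("EDC", "median", "ulnar")
TRIAL_TYPES = ("thumb", "index")

EPOCH_ORDER = (
    "task_before",
    "nerve_before",
    "paired",
    "nerve_after1",
    "task_after",
    "nerve_after2",
)
POST_EPOCHS = frozenset({"nerve_after1", "task_after", "nerve_after2"})

#: Gaussian kernels are evaluated on a +-4 sigma support.
KERNEL_SUPPORT_SIGMAS = 4.0


@dataclass(frozen=True)
class GaussComponent:
    """One Gaussian rate transient.

    ``latency`` is the component center relative to the aligning event in
    seconds (negative latencies describe activity leading up to trial
    completion), ``amplitude`` the peak rate contribution in spikes/s and
    ``sigma`` the Gaussian width in seconds.  ``label`` names the component
    ("early", "late", ...) so plasticity multipliers can address it.
    """

    latency: float
    amplitude: float
    sigma: float
    label: str = ""

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("component sigma must be positive")


@dataclass(frozen=True)
class ProtocolConfig:
    """Stimulation/behavior protocol parameters for one session.

    Defaults follow the experimental protocol: 300 stimuli per electrode at
    500 ms interstimulus interval in the nerve assessments, ~61 min of paired
    stimulation with interstimulus interval uniform on 80-120 ms, and 150
    task trials per behavioral epoch.
    """

    condition: str = "synchronous"
    nerve_assessment_count: int = 300
    nerve_assessment_isi: float = 0.5
    paired_duration: float = 3660.0
    paired_isi_range: tuple[float, float] = (0.080, 0.120)
    task_trials_per_epoch: int = 150
    task_error_probability: float = 0.15
    trial_interval: float = 8.0
    lever_fs: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        if self.condition not in ("synchronous", "asynchronous"):
            raise ValueError(f"unknown condition {self.condition!r}")
        lo, hi = self.paired_isi_range
        if not lo < hi:
            raise ValueError("paired_isi_range lower bound must be < upper bound")
        if lo <= 0:
            raise ValueError("paired interstimulus intervals must be positive")
        for name in ("nerve_assessment_count", "task_trials_per_epoch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.nerve_assessment_isi <= 0 or self.paired_duration <= 0:
            raise ValueError("durations must be positive")
        if not 0.0 <= self.task_error_probability <= 1.0:
            raise ValueError("task_error_probability must be in [0, 1]")


@dataclass(frozen=True)
class UnitGroundTruth:
    """Ground-truth rate model for one unit.

    ``stim_kernels`` maps electrode -> components of the stimulus-locked
    transient (the early component sits at ~7-12 ms, the late component at
    ~12-30 ms post-stimulus); ``task_profiles`` maps trial type -> components
    of the rate profile around trial completion (-500..+200 ms).

    Plasticity is multiplicative and applied only in post-intervention
    epochs: ``stim_plasticity[electrode][label]`` scales the matching kernel
    component, ``task_plasticity[trial_type]`` scales that trial type's
    profile.  Missing entries mean "unchanged" (multiplier 1).
    """

    baseline_rate: float = 15.0
    stim_kernels: Mapping[str, tuple[GaussComponent, ...]] = field(default_factory=dict)
    task_profiles: Mapping[str, tuple[GaussComponent, ...]] = field(default_factory=dict)
    stim_plasticity: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    task_plasticity: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        for mapping in self.stim_plasticity.values():
            for mult in mapping.values():
                if mult <= 0:
                    raise ValueError("plasticity multipliers must be > 0")
        for mult in self.task_plasticity.values():
            if mult <= 0:
                raise ValueError("plasticity multipliers must be > 0")

    def stim_multiplier(self, electrode: str, label: str, post: bool) -> float:
        if not post:
            return 1.0
        return float(self.stim_plasticity.get(electrode, {}).get(label, 1.0))

    def task_multiplier(self, trial_type: str, post: bool) -> float:
        if not post:
            return 1.0
        return float(self.task_plasticity.get(trial_type, 1.0))


def default_unit_truth(
    rng=None,
    *,
    baseline_rate: float = 15.0,
    early_amp: float = 90.0,
    late_amp: float = 45.0,
    task_amp: float = 30.0,
    stim_plasticity: Mapping[str, Mapping[str, float]] | None = None,
    task_plasticity: Mapping[str, float] | None = None,
) -> UnitGroundTruth:
    """A realistic default unit: early/late responses to median and ulnar
    stimulation, a weak EDC response, and distinct thumb/index task profiles.

    With ``rng`` given, latencies and amplitudes are jittered so a population
    of units is heterogeneous.
    """
    rng = as_generator(rng) if rng is not None else None

    def j(value, frac=0.15):
        if rng is None:
            return value
        return float(value * (1.0 + frac * (2.0 * rng.random() - 1.0)))

    def stim(early, late):
        comps = []
        if early > 0:
            comps.append(GaussComponent(j(0.009), j(early), 0.0015, "early"))
        if late > 0:
            comps.append(GaussComponent(j(0.020), j(late), 0.004, "late"))
        return tuple(comps)

    kernels = {
        "median": stim(early_amp, late_amp),
        "ulnar": stim(0.8 * early_amp, 0.8 * late_amp),
        "EDC": stim(0.25 * early_amp, 0.25 * late_amp),
    }
    profiles = {
        "thumb": (GaussComponent(j(-0.150), j(task_amp), 0.120),),
        "index": (GaussComponent(j(-0.250), j(0.7 * task_amp), 0.150),),
    }
    return UnitGroundTruth(
        baseline_rate=j(baseline_rate, 0.3),
        stim_kernels=kernels,
        task_profiles=profiles,
        stim_plasticity=stim_plasticity or {},
        task_plasticity=task_plasticity or {},
    )


@dataclass
class TrialRecord:
    """One behavioral trial: instruction, outcome and lever trajectories."""

    trial_id: int
    epoch: str
    instructed: str
    success: bool
    completion_time: float  # seconds; absolute within the session
    thumb_trace: np.ndarray  # degrees
    index_trace: np.ndarray  # degrees
    fs: float = 1000.0

    def __post_init__(self):
        if len(self.thumb_trace) != len(self.index_trace):
            raise ValueError("thumb and index traces must have equal length")


@dataclass
class SessionArchive:
    """All epochs, units, stimulus events and trials for one experiment."""

    condition: str
    epochs: dict[str, tuple[float, float]]
    units: list[dict[str, np.ndarray]]  # per unit: epoch -> spike times (absolute s)
    stim_events: pd.DataFrame  # columns: epoch, electrode, time_s
    trials: list[TrialRecord]
    config: ProtocolConfig | None = None

    def unit_spikes(self, unit: int, epoch: str) -> np.ndarray:
        return self.units[unit][epoch]

    def events(self, epoch: str, electrode: str) -> np.ndarray:
        df = self.stim_events
        sel = (df["epoch"] == epoch) & (df["electrode"] == electrode)
        return df.loc[sel, "time_s"].to_numpy()

    def epoch_trials(self, epoch: str) -> list[TrialRecord]:
        return [t for t in self.trials if t.epoch == epoch]

    def completion_times(self, epoch: str, trial_type: str, successful_only: bool = True) -> np.ndarray:
        times = [
            t.completion_time
            for t in self.trials
            if t.epoch == epoch
            and t.instructed == trial_type
            and (t.success or not successful_only)
        ]
        return np.asarray(times, dtype=float)


# ---------------------------------------------------------------------------
# lever trajectories

# Success thresholds in degrees: the instructed digit must exceed its
# minimal-motion threshold while the noninstructed digit stays below its
# maximal-motion threshold.
INSTRUCTED_MIN_DEG = {"thumb": 7.0, "index": 8.0}
NONINSTRUCTED_MAX_DEG = {"thumb": 11.0, "index": 17.0}  # keyed by instructed digit
# noninstructed-digit peaks: kept clear of the thresholds by more than the
# smooth-noise amplitude so trial outcome is exact by construction
_LEVER_NOISE_DEG = 0.2
_PEAK_RANGES = {
    # instructed -> (instructed peak range, noninstructed peak success range,
    #                noninstructed peak failure range)
    "thumb": ((9.0, 14.0), (1.0, 5.0), (11.5, 16.0)),
    "index": ((9.5, 14.0), (5.0, 10.0), (17.5, 22.0)),
}


def _min_jerk_ramp(n: int) -> np.ndarray:
    """Minimum-jerk position profile from 0 to 1 over n samples."""
    tau = np.linspace(0.0, 1.0, n)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _lever_trace(peak: float, n_total: int, n_rest: int, n_move: int, rng) -> np.ndarray:
    trace = np.zeros(n_total)
    ramp = _min_jerk_ramp(n_move) * peak
    trace[n_rest : n_rest + n_move] = ramp
    trace[n_rest + n_move :] = peak
    # smooth low-frequency wobble, bounded well below the threshold margins
    t = np.arange(n_total) / n_total
    wobble = sum(
        rng.uniform(-1, 1) * np.sin(2 * np.pi * (k * t + rng.random()))
        for k in (1, 2, 3)
    )
    trace += _LEVER_NOISE_DEG / 3.0 * np.asarray(wobble) * np.minimum(1.0, trace / max(peak, 1e-9))
    return trace


def generate_lever_traces(
    instructed: str,
    error_probability: float = 0.0,
    seed=0,
    *,
    fs: float = 1000.0,
) -> TrialRecord:
    """Generate one trial's thumb/index lever trajectories.

    With probability ``1 - error_probability`` the traces satisfy the success
    rule for the instructed digit; otherwise the noninstructed digit crosses
    its maximal-motion threshold (the failure mode scored as an error).
    """
    if instructed not in TRIAL_TYPES:
        raise ValueError(f"unknown instructed digit {instructed!r}")
    if not 0.0 <= error_probability <= 1.0:
        raise ValueError("error_probability must be in [0, 1]")
    rng = as_generator(seed)
    success = bool(rng.random() >= error_probability)

    n_rest = int(0.3 * fs)
    n_move = int(0.5 * fs)
    n_total = int(1.5 * fs)
    inst_range, non_ok, non_bad = _PEAK_RANGES[instructed]
    inst_peak = rng.uniform(*inst_range)
    non_peak = rng.uniform(*(non_ok if success else non_bad))

    inst_trace = _lever_trace(inst_peak, n_total, n_rest, n_move, rng)
    non_trace = _lever_trace(non_peak, n_total, n_rest, n_move, rng)
    thumb, index = (inst_trace, non_trace) if instructed == "thumb" else (non_trace, inst_trace)
    completion = (n_rest + n_move) / fs
    return TrialRecord(
        trial_id=-1,
        epoch="",
        instructed=instructed,
        success=success,
        completion_time=completion,
        thumb_trace=thumb,
        index_trace=index,
        fs=fs,
    )


# ---------------------------------------------------------------------------
# event schedules


def _nerve_epoch_events(start: float, config: ProtocolConfig, rng) -> pd.DataFrame:
    """Randomized interleaving of the three electrodes at a fixed ISI."""
    n = config.nerve_assessment_count
    electrodes = np.repeat(np.array(ELECTRODES, dtype=object), n)
    rng.shuffle(electrodes)
    times = start + 1.0 + config.nerve_assessment_isi * np.arange(3 * n)
    return pd.DataFrame({"electrode": electrodes, "time_s": times})


def _paired_epoch_events(start: float, stop: float, config: ProtocolConfig, rng) -> pd.DataFrame:
    lo, hi = config.paired_isi_range
    duration = stop - start - 2.0
    n_max = int(duration / lo) + 2
    intervals = rng.uniform(lo, hi, size=n_max)
    median_times = start + 1.0 + np.concatenate([[0.0], np.cumsum(intervals[:-1])])
    keep = median_times + hi < stop
    median_times, intervals = median_times[keep], intervals[keep]
    if config.condition == "synchronous":
        ulnar_times = median_times.copy()
    else:
        ulnar_times = median_times + intervals / 2.0
    frames = [
        pd.DataFrame({"electrode": "median", "time_s": median_times}),
        pd.DataFrame({"electrode": "ulnar", "time_s": ulnar_times}),
    ]
    return pd.concat(frames, ignore_index=True).sort_values("time_s", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# inhomogeneous Poisson sampling (thinning)


def _component_bounds(truth: UnitGroundTruth, post: bool,
                      electrodes_present, types_present) -> tuple[float, float]:
    """Conservative (min, max) total deviation from baseline for one epoch,
    summing only the components whose aligning events occur in that epoch."""
    lo = hi = 0.0
    for electrode in electrodes_present:
        for comp in truth.stim_kernels.get(electrode, ()):
            a = comp.amplitude * truth.stim_multiplier(electrode, comp.label, post)
            lo += min(a, 0.0)
            hi += max(a, 0.0)
    for trial_type in types_present:
        for comp in truth.task_profiles.get(trial_type, ()):
            a = comp.amplitude * truth.task_multiplier(trial_type, post)
            lo += min(a, 0.0)
            hi += max(a, 0.0)
    return lo, hi


def _neighbor_contribution(t: np.ndarray, events: np.ndarray, comps, mults) -> np.ndarray:
    """Sum of component rates at times ``t`` from the nearest events.

    Assumes component support is shorter than the event spacing, so only the
    immediately preceding and following events can contribute.
    """
    out = np.zeros_like(t)
    if len(events) == 0 or not comps:
        return out
    idx = np.searchsorted(events, t, side="right")
    for shift in (0, 1):  # preceding event, next event
        j = idx - 1 + shift
        valid = (j >= 0) & (j < len(events))
        if not np.any(valid):
            continue
        dt = t[valid] - events[np.clip(j, 0, len(events) - 1)][valid]
        contrib = np.zeros_like(dt)
        for comp, mult in zip(comps, mults):
            span = KERNEL_SUPPORT_SIGMAS * comp.sigma
            near = np.abs(dt - comp.latency) <= span
            if np.any(near):
                x = dt[near] - comp.latency
                contrib[near] += comp.amplitude * mult * np.exp(-0.5 * (x / comp.sigma) ** 2)
        out[valid] += contrib
    return out


def _epoch_rate(t: np.ndarray, epoch: str, truth: UnitGroundTruth,
                events_by_electrode: Mapping[str, np.ndarray],
                completions_by_type: Mapping[str, np.ndarray]) -> np.ndarray:
    post = epoch in POST_EPOCHS
    rate = np.full_like(t, truth.baseline_rate)
    for electrode, ev in events_by_electrode.items():
        comps = truth.stim_kernels.get(electrode, ())
        mults = [truth.stim_multiplier(electrode, c.label, post) for c in comps]
        rate += _neighbor_contribution(t, ev, comps, mults)
    for trial_type, completions in completions_by_type.items():
        comps = truth.task_profiles.get(trial_type, ())
        mults = [truth.task_multiplier(trial_type, post) for _ in comps]
        rate += _neighbor_contribution(t, completions, comps, mults)
    return rate


def _sample_epoch_spikes(epoch: str, start: float, stop: float, truth: UnitGroundTruth,
                         events_by_electrode, completions_by_type, rng) -> np.ndarray:
    lo, hi = _component_bounds(
        truth,
        epoch in POST_EPOCHS,
        [el for el, ev in events_by_electrode.items() if len(ev)],
        [tt for tt, c in completions_by_type.items() if len(c)],
    )
    if truth.baseline_rate + lo < 0:
        raise ValueError(
            "ground-truth configuration allows a negative instantaneous rate "
            f"(baseline {truth.baseline_rate} + worst-case deviation {lo})"
        )
    ceiling = truth.baseline_rate + hi
    if ceiling <= 0:
        return np.empty(0)
    n_cand = rng.poisson(ceiling * (stop - start))
    if n_cand == 0:
        return np.empty(0)
    cand = np.sort(rng.uniform(start, stop, size=n_cand))
    accept_u = rng.uniform(0.0, 1.0, size=n_cand)
    rate = _epoch_rate(cand, epoch, truth, events_by_electrode, completions_by_type)
    return cand[accept_u * ceiling < rate]


# ---------------------------------------------------------------------------
# session assembly


def generate_session(
    protocol: ProtocolConfig,
    truths: Sequence[UnitGroundTruth],
    *,
    epochs: Sequence[str] | None = None,
) -> SessionArchive:
    """Generate a full SessionArchive from the protocol and unit truths.

    ``epochs`` restricts which epochs are populated with events/trials/spikes
    (all six by default); the epoch timeline always covers the full design.
    Deterministic given ``protocol.seed``.
    """
    if len(truths) == 0:
        raise ValueError("at least one unit ground truth is required")
    wanted = set(EPOCH_ORDER if epochs is None else epochs)
    unknown = wanted - set(EPOCH_ORDER)
    if unknown:
        raise ValueError(f"unknown epochs {sorted(unknown)}")

    nerve_dur = 3 * protocol.nerve_assessment_count * protocol.nerve_assessment_isi + 2.0
    task_dur = protocol.task_trials_per_epoch * protocol.trial_interval + 2.0
    durations = {
        "task_before": task_dur,
        "nerve_before": nerve_dur,
        "paired": protocol.paired_duration,
        "nerve_after1": nerve_dur,
        "task_after": task_dur,
        "nerve_after2": nerve_dur,
    }
    gap = 10.0
    epoch_bounds: dict[str, tuple[float, float]] = {}
    t0 = 0.0
    for name in EPOCH_ORDER:
        epoch_bounds[name] = (t0, t0 + durations[name])
        t0 += durations[name] + gap

    ev_rng = substream(protocol.seed, "events")
    event_frames = []
    for name in ("nerve_before", "nerve_after1", "nerve_after2"):
        if name in wanted:
            df = _nerve_epoch_events(epoch_bounds[name][0], protocol, ev_rng)
            df.insert(0, "epoch", name)
            event_frames.append(df)
    if "paired" in wanted:
        df = _paired_epoch_events(*epoch_bounds["paired"], protocol, ev_rng)
        df.insert(0, "epoch", "paired")
        event_frames.append(df)
    if event_frames:
        stim_events = pd.concat(event_frames, ignore_index=True)
        stim_events = stim_events.sort_values("time_s", kind="stable").reset_index(drop=True)
    else:
        stim_events = pd.DataFrame({"epoch": [], "electrode": [], "time_s": []})

    lever_rng = substream(protocol.seed, "levers")
    trials: list[TrialRecord] = []
    trial_id = 0
    for name in ("task_before", "task_after"):
        if name not in wanted:
            continue
        start = epoch_bounds[name][0]
        n = protocol.task_trials_per_epoch
        instructed = np.repeat(np.array(TRIAL_TYPES, dtype=object), (n + 1) // 2)[:n]
        lever_rng.shuffle(instructed)
        for i, digit in enumerate(instructed):
            rec = generate_lever_traces(
                str(digit), protocol.task_error_probability, lever_rng, fs=protocol.lever_fs
            )
            rec.trial_id = trial_id
            rec.epoch = name
            rec.completion_time += start + 2.0 + i * protocol.trial_interval
            trials.append(rec)
            trial_id += 1

    units = []
    for u, truth in enumerate(truths):
        spike_rng = substream(protocol.seed, f"spikes-unit{u}")
        spikes_by_epoch: dict[str, np.ndarray] = {}
        for name in EPOCH_ORDER:
            if name not in wanted:
                spikes_by_epoch[name] = np.empty(0)
                continue
            start, stop = epoch_bounds[name]
            ev_by_el = {
                el: stim_events.loc[
                    (stim_events["epoch"] == name) & (stim_events["electrode"] == el),
                    "time_s",
                ].to_numpy()
                for el in ELECTRODES
            }
            completions = {
                tt: np.asarray(
                    [t.completion_time for t in trials if t.epoch == name and t.instructed == tt]
                )
                for tt in TRIAL_TYPES
            }
            spikes_by_epoch[name] = _sample_epoch_spikes(
                name, start, stop, truth, ev_by_el, completions, spike_rng
            )
        units.append(spikes_by_epoch)

    return SessionArchive(
        condition=protocol.condition,
        epochs=epoch_bounds,
        units=units,
        stim_events=stim_events,
        trials=trials,
        config=protocol,
    )


# ---------------------------------------------------------------------------
# raw traces (fixture for the detection stage)


def generate_raw_trace(
    truth: UnitGroundTruth,
    noise_sd: float,
    template: np.ndarray,
    duration: float,
    seed=0,
    *,
    fs: float = 25000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian noise with a spike waveform template added at Poisson times.

    Spike times are homogeneous Poisson at ``truth.baseline_rate``.
    Overlapping templates sum.  Returns ``(trace, true_spike_times)``.
    """
    template = np.asarray(template, dtype=float)
    if template.size < 1:
        raise ValueError("template must contain at least one sample")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = as_generator(seed)
    n = int(round(duration * fs))
    trace = rng.normal(0.0, noise_sd, size=n)
    n_spikes = rng.poisson(truth.baseline_rate * duration)
    spike_times = np.sort(rng.uniform(0.0, duration, size=n_spikes))
    # drop spikes whose template would run past the end of the trace
    spike_times = spike_times[(spike_times * fs).astype(int) + template.size <= n]
    for t in spike_times:
        i = int(t * fs)
        trace[i : i + template.size] += template
    return trace, spike_times


# ---------------------------------------------------------------------------
# archive I/O


def save_session(archive: SessionArchive, out_dir) -> None:
    """Write a session archive as a directory of CSVs plus metadata.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "condition": archive.condition,
        "epochs": {k: list(v) for k, v in archive.epochs.items()},
        "config": dataclasses.asdict(archive.config) if archive.config else None,
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2))

    unit_rows = []
    for u, spikes_by_epoch in enumerate(archive.units):
        for epoch, spikes in spikes_by_epoch.items():
            for t in spikes:
                unit_rows.append((u, epoch, t))
    pd.DataFrame(unit_rows, columns=["unit_id", "epoch", "spike_time_s"]).to_csv(
        out / "units.csv", index=False
    )
    archive.stim_events.to_csv(out / "events.csv", index=False)

    trial_rows = [
        (t.trial_id, t.epoch, t.instructed, t.success, t.completion_time)
        for t in archive.trials
    ]
    pd.DataFrame(
        trial_rows, columns=["trial_id", "epoch", "instructed", "success", "completion_time_s"]
    ).to_csv(out / "trials.csv", index=False)

    lever_frames = []
    for t in archive.trials:
        lever_frames.append(
            pd.DataFrame(
                {
                    "trial_id": t.trial_id,
                    "sample_index": np.arange(len(t.thumb_trace)),
                    "thumb_deg": t.thumb_trace,
                    "index_deg": t.index_trace,
                }
            )
        )
    if lever_frames:
        pd.concat(lever_frames, ignore_index=True).to_csv(out / "levers.csv", index=False)
    else:
        pd.DataFrame(columns=["trial_id", "sample_index", "thumb_deg", "index_deg"]).to_csv(
            out / "levers.csv", index=False
        )


def load_session(in_dir) -> SessionArchive:
    """Load a session archive written by :func:`save_session`."""
    src = Path(in_dir)
    meta = json.loads((src / "metadata.json").read_text())
    epochs = {k: (float(v[0]), float(v[1])) for k, v in meta["epochs"].items()}
    config = None
    if meta.get("config"):
        cfg = dict(meta["config"])
        cfg["paired_isi_range"] = tuple(cfg["paired_isi_range"])
        config = ProtocolConfig(**cfg)

    units_df = pd.read_csv(src / "units.csv")
    n_units = int(units_df["unit_id"].max()) + 1 if len(units_df) else 0
    units = []
    for u in range(n_units):
        sub = units_df[units_df["unit_id"] == u]
        units.append(
            {
                epoch: np.sort(sub.loc[sub["epoch"] == epoch, "spike_time_s"].to_numpy())
                for epoch in EPOCH_ORDER
            }
        )
    stim_events = pd.read_csv(src / "events.csv")

    trials_df = pd.read_csv(src / "trials.csv")
    levers_df = pd.read_csv(src / "levers.csv")
    fs = float(meta["config"]["lever_fs"]) if meta.get("config") else 1000.0
    trials = []
    for _, row in trials_df.iterrows():
        lv = levers_df[levers_df["trial_id"] == row["trial_id"]].sort_values("sample_index")
        trials.append(
            TrialRecord(
                trial_id=int(row["trial_id"]),
                epoch=str(row["epoch"]),
                instructed=str(row["instructed"]),
                success=bool(row["success"]),
                completion_time=float(row["completion_time_s"]),
                thumb_trace=lv["thumb_deg"].to_numpy(),
                index_trace=lv["index_deg"].to_numpy(),
                fs=fs,
            )
        )
    return SessionArchive(
        condition=meta["condition"],
        epochs=epochs,
        units=units,
        stim_events=stim_events,
        trials=trials,
        config=config,
    )
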