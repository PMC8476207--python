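"""End-to-end orchestration of the six-epoch analysis.

``run_full`` takes a session archive (simulated or ingested) and produces
the standard report tables: behavioral metrics per epoch, task-modulation
shuffle tests per unit, population Z panels for the nerve and task
assessments, decoding accuracies with population tests, and the
recording-instability control.  All randomness is seeded through named
substreams of the pipeline seed, so identical config + archive give
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from pairedstim import histograms as hg
from pairedstim import zscores as zs
from pairedstim._rng import substream
from pairedstim.behavior import score_epoch
from pairedstim.decoding import (
    accuracy_change_mc_test,
    loo_lda,
    population_accuracy_tests,
    rate_features,
)
from pairedstim.inference import instability_control
from pairedstim.synthetic import ELECTRODES, TRIAL_TYPES, SessionArchive

logger = logging.getLogger(__name__)

NERVE_COMPARISONS = (("nerve_before", "nerve_after1"), ("nerve_before", "nerve_after2"))
NERVE_PAIRS = (("median", "ulnar"), ("EDC", "median"), ("EDC", "ulnar"))


@dataclass
class PipelineConfig:
    """Analysis defaults for the full pipeline.

    Kernel widths follow the plateau of the decoding accuracy vs kernel
    width sweep: 3 ms for stimulus decoding, 190 ms for task decoding.
    """

    stim_kernel_width: float = 0.003
    task_kernel_width: float = 0.190
    psth_window: tuple[float, float] = hg.PSTH_WINDOW
    psth_bin_width: float = hg.PSTH_BIN_WIDTH
    peth_window: tuple[float, float] = hg.PETH_WINDOW
    peth_bin_width: float = hg.PETH_BIN_WIDTH
    fdr_q: float = 0.05
    n_shuffles: int = 1000
    unit_mc: bool = False  # per-unit accuracy-change Monte Carlo tests
    n_unit_mc: int = 1000
    shrinkage: float = 0.1
    seed: int = 0
    make_figures: bool = False

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _behavior_table(archive: SessionArchive) -> pd.DataFrame:
    rows = []
    for epoch in ("task_before", "task_after"):
        trials = archive.epoch_trials(epoch)
        if not trials:
            continue
        start, stop = archive.epochs[epoch]
        metrics = score_epoch(trials, (stop - start) / 60.0)
        row = {"epoch": epoch, "c": metrics.c, "e": metrics.e,
               "A": metrics.A, "s": metrics.s, "t_min": metrics.t}
        for digit, sub in metrics.per_digit.items():
            row[f"A_{digit}"] = sub["A"]
            row[f"e_{digit}"] = sub["e"]
        rows.append(row)
    return pd.DataFrame(rows)


def _modulation_table(archive: SessionArchive, config: PipelineConfig) -> pd.DataFrame:
    rows = []
    for u in range(len(archive.units)):
        spikes = archive.unit_spikes(u, "task_before")
        for trial_type in TRIAL_TYPES:
            completions = archive.completion_times("task_before", trial_type)
            if completions.size == 0:
                continue
            trial_spikes = hg.per_trial_spikes(spikes, completions, config.peth_window)
            test = hg.shuffle_modulation_test(
                trial_spikes,
                window=config.peth_window,
                bin_width=config.peth_bin_width,
                n_shuffles=config.n_shuffles,
                seed=substream(config.seed, f"shuffle-u{u}-{trial_type}"),
            )
            rows.append(
                {"unit_id": u, "trial_type": trial_type,
                 "peak_modulation": test.peak_modulation,
                 "exceedance_rank": test.exceedance_rank,
                 "significant": test.significant}
            )
    return pd.DataFrame(rows)


def _nerve_z_tables(archive: SessionArchive, config: PipelineConfig):
    """Per-unit and population stimulus Z series for each electrode and
    post-intervention assessment."""
    tables = {}
    for before_ep, after_ep in NERVE_COMPARISONS:
        for electrode in ELECTRODES:
            ev_before = archive.events(before_ep, electrode)
            ev_after = archive.events(after_ep, electrode)
            if ev_before.size == 0 or ev_after.size == 0:
                continue
            series = []
            for u in range(len(archive.units)):
                hb = hg.build_psth(archive.unit_spikes(u, before_ep), ev_before,
                                   window=config.psth_window, bin_width=config.psth_bin_width)
                ha = hg.build_psth(archive.unit_spikes(u, after_ep), ev_after,
                                   window=config.psth_window, bin_width=config.psth_bin_width)
                series.append(zs.z_stimulus(hb, ha))
            pop = zs.z_population(series)
            tables[(before_ep, after_ep, electrode)] = {"units": series, "population": pop}
    return tables


def _task_z_tables(archive: SessionArchive, config: PipelineConfig):
    tables = {}
    for trial_type in TRIAL_TYPES:
        t_before = archive.completion_times("task_before", trial_type)
        t_after = archive.completion_times("task_after", trial_type)
        if t_before.size == 0 or t_after.size == 0:
            continue
        series = []
        for u in range(len(archive.units)):
            hb = hg.build_peth(archive.unit_spikes(u, "task_before"), t_before,
                               window=config.peth_window, bin_width=config.peth_bin_width)
            ha = hg.build_peth(archive.unit_spikes(u, "task_after"), t_after,
                               window=config.peth_window, bin_width=config.peth_bin_width)
            series.append(zs.z_task(hb, ha))
        pop = zs.z_population(series)
        tables[trial_type] = {"units": series, "population": pop}
    return tables


def _nerve_features(archive, unit, epoch, pair, config):
    trial_spikes, labels = [], []
    spikes = archive.unit_spikes(unit, epoch)
    for electrode in pair:
        events = archive.events(epoch, electrode)
        trial_spikes.extend(hg.per_trial_spikes(spikes, events, config.psth_window))
        labels.extend([electrode] * len(events))
    return rate_features(trial_spikes, labels, window=config.psth_window,
                         bin_width=config.psth_bin_width,
                         kernel_width=config.stim_kernel_width)


def _task_features(archive, unit, epoch, config):
    trial_spikes, labels = [], []
    spikes = archive.unit_spikes(unit, epoch)
    for trial_type in TRIAL_TYPES:
        completions = archive.completion_times(epoch, trial_type)
        trial_spikes.extend(hg.per_trial_spikes(spikes, completions, config.peth_window))
        labels.extend([trial_type] * len(completions))
    return rate_features(trial_spikes, labels, window=config.peth_window,
                         bin_width=config.peth_bin_width,
                         kernel_width=config.task_kernel_width)


def _decoding_table(archive: SessionArchive, config: PipelineConfig) -> pd.DataFrame:
    rows = []
    n_units = len(archive.units)
    for u in range(n_units):
        for before_ep, after_ep in NERVE_COMPARISONS:
            for pair in NERVE_PAIRS:
                try:
                    fb = _nerve_features(archive, u, before_ep, pair, config)
                    fa = _nerve_features(archive, u, after_ep, pair, config)
                except ValueError:
                    continue
                if fb.n_trials == 0 or fa.n_trials == 0:
                    continue
                row = {
                    "unit_id": u,
                    "comparison": "-".join(pair),
                    "epoch_pair": f"{before_ep}:{after_ep}",
                    "accuracy_before": loo_lda(fb, shrinkage=config.shrinkage).accuracy,
                    "accuracy_after": loo_lda(fa, shrinkage=config.shrinkage).accuracy,
                }
                if config.unit_mc:
                    mc = accuracy_change_mc_test(
                        fb, fa, n_mc=config.n_unit_mc,
                        seed=substream(config.seed, f"mc-u{u}-{row['comparison']}-{after_ep}"),
                        shrinkage=config.shrinkage,
                    )
                    row["mc_p"] = mc.p_value
                    row["mc_direction"] = mc.direction
                rows.append(row)
        if archive.completion_times("task_before", "thumb").size and archive.completion_times(
            "task_after", "thumb"
        ).size:
            fb = _task_features(archive, u, "task_before", config)
            fa = _task_features(archive, u, "task_after", config)
            row = {
                "unit_id": u,
                "comparison": "thumb-index",
                "epoch_pair": "task_before:task_after",
                "accuracy_before": loo_lda(fb, shrinkage=config.shrinkage).accuracy,
                "accuracy_after": loo_lda(fa, shrinkage=config.shrinkage).accuracy,
            }
            if config.unit_mc:
                mc = accuracy_change_mc_test(
                    fb, fa, n_mc=config.n_unit_mc,
                    seed=substream(config.seed, f"mc-u{u}-task"),
                    shrinkage=config.shrinkage,
                )
                row["mc_p"] = mc.p_value
                row["mc_direction"] = mc.direction
            rows.append(row)
    return pd.DataFrame(rows)


def _rate_change_table(archive: SessionArchive) -> pd.DataFrame:
    """Mean firing-rate change per unit across epochs (instability marker)."""
    rows = []
    for u in range(len(archive.units)):
        rates = {}
        for epoch, (start, stop) in archive.epochs.items():
            spikes = archive.unit_spikes(u, epoch)
            rates[epoch] = len(spikes) / max(stop - start, 1e-9)
        rows.append({"unit_id": u, **{f"rate_{k}": v for k, v in rates.items()}})
    return pd.DataFrame(rows)


def run_full(archive: SessionArchive, config: PipelineConfig | None = None,
             out_dir=None) -> dict:
    """Run the full analysis on one session archive.

    Returns a report bundle (dict of tables / Z-series structures); when
    ``out_dir`` is given, tables are also written as CSVs (and Z panels as
    PNGs when ``config.make_figures``).
    """
    config = config or PipelineConfig()
    logger.info("pipeline start: config hash %s", config.config_hash())

    bundle: dict = {"config_hash": config.config_hash()}
    bundle["behavior"] = _behavior_table(archive)
    bundle["modulation"] = _modulation_table(archive, config)
    bundle["z_stimulus"] = _nerve_z_tables(archive, config)
    bundle["z_task"] = _task_z_tables(archive, config)
    bundle["decoding"] = _decoding_table(archive, config)
    if len(bundle["decoding"]):
        counts = bundle["decoding"].groupby("comparison").size()
        if counts.min() >= 5:
            grouped = bundle["decoding"].groupby(["comparison", "epoch_pair"]).size()
            # population tests per comparison x epoch pair
            pieces = []
            for (comparison, epoch_pair), _ in grouped.items():
                sel = bundle["decoding"][
                    (bundle["decoding"]["comparison"] == comparison)
                    & (bundle["decoding"]["epoch_pair"] == epoch_pair)
                ].copy()
                sel["comparison"] = f"{comparison}|{epoch_pair}"
                pieces.append(sel)
            try:
                bundle["population_tests"] = population_accuracy_tests(
                    pd.concat(pieces, ignore_index=True), q=config.fdr_q
                )
            except ValueError:
                bundle["population_tests"] = None

    rates = _rate_change_table(archive)
    bundle["rate_changes"] = rates
    if len(bundle["decoding"]) and len(rates) >= 3:
        merged = bundle["decoding"].merge(rates, on="unit_id")
        controls = []
        for comparison, grp in merged.groupby("comparison"):
            if len(grp) < 3:
                continue
            before_ep = grp["epoch_pair"].str.split(":").str[0].iloc[0]
            after_ep = grp["epoch_pair"].str.split(":").str[1].iloc[0]
            dr = grp[f"rate_{after_ep}"] - grp[f"rate_{before_ep}"]
            da = grp["accuracy_after"] - grp["accuracy_before"]
            res = instability_control(dr.to_numpy(), da.to_numpy())
            controls.append({"comparison": comparison, "r2": res.r2,
                             "p": res.p_value, "degenerate": res.degenerate})
        bundle["instability"] = pd.DataFrame(controls)

    if out_dir is not None:
        _write_bundle(bundle, out_dir, config)
    return bundle


def _write_bundle(bundle: dict, out_dir, config: PipelineConfig) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("behavior", "modulation", "decoding", "population_tests",
                 "rate_changes", "instability"):
        obj = bundle.get(name)
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out / f"{name}.csv", index=False)
    for key, entry in bundle.get("z_stimulus", {}).items():
        before_ep, after_ep, electrode = key
        entry["population"].to_frame().to_csv(
            out / f"z_stim_{electrode}_{after_ep}.csv", index=False
        )
    for trial_type, entry in bundle.get("z_task", {}).items():
        entry["population"].to_frame().to_csv(out / f"z_task_{trial_type}.csv", index=False)
    (out / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, default=str)
    )
    if config.make_figures:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for key, entry in bundle.get("z_stimulus", {}).items():
            _, after_ep, electrode = key
            ax = zs.plot_zseries(entry["population"], title=f"{electrode} {after_ep}")
            ax.figure.savefig(out / f"z_stim_{electrode}_{after_ep}.png", dpi=120)
            plt.close(ax.figure)
        for trial_type, entry in bundle.get("z_task", {}).items():
            ax = zs.plot_zseries(entry["population"], title=f"task {trial_type}")
            ax.figure.savefig(out / f"z_task_{trial_type}.png", dpi=120)
            plt.close(ax.figure)
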