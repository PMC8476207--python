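"""Tests of the synthetic session generator against its stated protocol."""

import numpy as np
import pytest
from scipy import stats

from pairedstim.behavior import classify_trial
from pairedstim.histograms import build_psth, psth_blank_mask
from pairedstim.synthetic import (
    GaussComponent,
    ProtocolConfig,
    UnitGroundTruth,
    default_unit_truth,
    generate_lever_traces,
    generate_raw_trace,
    generate_session,
    load_session,
    save_session,
)

from conftest import flat_unit, single_kernel_unit, small_protocol


class TestEventSchedules:
    def test_nerve_assessment_has_300_stimuli_per_electrode(self):
        """The default protocol delivers exactly 300 stimuli per electrode at
        500 ms interstimulus interval, in randomized order."""
        arc = generate_session(ProtocolConfig(seed=3), [flat_unit()],
                               epochs=["nerve_before"])
        times = arc.stim_events["time_s"].to_numpy()
        for electrode in ("EDC", "median", "ulnar"):
            assert len(arc.events("nerve_before", electrode)) == 300
        assert np.allclose(np.diff(np.sort(times)), 0.5)
        # randomized order: not three contiguous blocks
        order = arc.stim_events["electrode"].to_numpy()
        assert len(np.unique(order[:10])) > 1

    def test_synchronous_paired_pulses_coincide(self):
        proto = small_protocol(condition="synchronous", paired_duration=30.0)
        arc = generate_session(proto, [flat_unit()], epochs=["paired"])
        assert np.array_equal(arc.events("paired", "median"),
                              arc.events("paired", "ulnar"))

    def test_asynchronous_second_nerve_at_interval_midpoint(self):
        proto = small_protocol(condition="asynchronous", paired_duration=30.0)
        arc = generate_session(proto, [flat_unit()], epochs=["paired"])
        m = arc.events("paired", "median")
        u = arc.events("paired", "ulnar")
        assert np.allclose(u[:-1], m[:-1] + np.diff(m) / 2.0)

    def test_paired_intervals_uniform_on_configured_range(self):
        proto = ProtocolConfig(seed=11, paired_duration=1100.0)
        arc = generate_session(proto, [flat_unit()], epochs=["paired"])
        isi = np.diff(arc.events("paired", "median"))
        assert len(isi) >= 10000
        assert stats.kstest(isi, "uniform", args=(0.080, 0.040)).pvalue > 0.01
        assert isi.min() >= 0.080 and isi.max() <= 0.120

    def test_epoch_order_and_event_containment(self, small_session):
        names = list(small_session.epochs)
        assert names == ["task_before", "nerve_before", "paired",
                         "nerve_after1", "task_after", "nerve_after2"]
        for _, row in small_session.stim_events.iterrows():
            start, stop = small_session.epochs[row["epoch"]]
            assert start <= row["time_s"] <= stop
        for u in range(len(small_session.units)):
            for epoch, (start, stop) in small_session.epochs.items():
                spikes = small_session.unit_spikes(u, epoch)
                if spikes.size:
                    assert spikes.min() >= start and spikes.max() <= stop


class TestSpikeStatistics:
    def test_psth_converges_to_specified_kernel(self):
        """With many stimuli the empirical PSTH matches baseline + kernel
        within sampling error in every unblanked bin."""
        truth = single_kernel_unit(latency=0.010, amplitude=80.0, sigma=0.002,
                                   baseline=12.0)
        proto = ProtocolConfig(seed=5, nerve_assessment_count=10000)
        arc = generate_session(proto, [truth], epochs=["nerve_before"])
        events = arc.events("nerve_before", "median")
        assert len(events) == 10000
        hist = build_psth(arc.unit_spikes(0, "nerve_before"), events)
        starts = hist.bin_starts
        comp = truth.stim_kernels["median"][0]
        # exact Gaussian mass per bin
        area = comp.amplitude * comp.sigma * np.sqrt(2 * np.pi)
        mass = area * np.diff(stats.norm.cdf(np.append(starts, 0.100),
                                             loc=comp.latency, scale=comp.sigma))
        expected = truth.baseline_rate * hist.bin_width + mass
        expected_counts = expected * hist.n_trials
        se = np.sqrt(expected_counts)
        keep = ~hist.blank_mask
        dev = np.abs(hist.counts[keep] - expected_counts[keep]) / se[keep]
        # per-bin agreement at sampling accuracy: a systematic kernel
        # mismatch would push many bins far out, whereas ~0.3 chance
        # excursions beyond 3 SE are expected among 112 Poisson bins
        assert np.all(dev <= 4.0)
        assert np.sum(dev > 3.0) <= 2
        assert abs(np.mean(hist.counts[keep] - expected_counts[keep])) < 0.5 * se[keep].mean()

    def test_plasticity_multiplier_scales_post_epoch_response(self):
        truth = single_kernel_unit(amplitude=120.0, multiplier=2.0)
        proto = small_protocol(nerve_assessment_count=1500)
        arc = generate_session(proto, [truth], epochs=["nerve_before", "nerve_after1"])
        resp = {}
        for epoch in ("nerve_before", "nerve_after1"):
            h = build_psth(arc.unit_spikes(0, epoch), arc.events(epoch, "median"))
            window = ~h.blank_mask & (h.bin_starts >= 0.007) & (h.bin_starts <= 0.014)
            baseline = h.rates()[~h.blank_mask & (h.bin_starts < -0.001)].mean()
            resp[epoch] = (h.rates()[window] - baseline).sum()
        ratio = resp["nerve_after1"] / resp["nerve_before"]
        assert 1.7 < ratio < 2.3

    def test_negative_rate_configuration_rejected(self):
        truth = UnitGroundTruth(
            baseline_rate=5.0,
            stim_kernels={"median": (GaussComponent(0.010, -50.0, 0.002, "dip"),)},
        )
        with pytest.raises(ValueError, match="negative instantaneous rate"):
            generate_session(small_protocol(), [truth], epochs=["nerve_before"])

    def test_determinism_and_archive_roundtrip(self, tmp_path):
        proto = small_protocol(seed=21)
        truths = [default_unit_truth(np.random.default_rng(0))]
        a = generate_session(proto, truths)
        b = generate_session(proto, truths)
        for epoch in a.epochs:
            assert np.array_equal(a.unit_spikes(0, epoch), b.unit_spikes(0, epoch))
        save_session(a, tmp_path / "arc")
        c = load_session(tmp_path / "arc")
        assert c.condition == a.condition
        assert len(c.trials) == len(a.trials)
        np.testing.assert_allclose(
            c.unit_spikes(0, "nerve_before"), a.unit_spikes(0, "nerve_before")
        )
        np.testing.assert_allclose(
            c.events("paired", "ulnar"), a.events("paired", "ulnar")
        )
        assert c.trials[0].success == a.trials[0].success
        np.testing.assert_allclose(c.trials[0].thumb_trace, a.trials[0].thumb_trace)


class TestLeverTraces:
    @pytest.mark.parametrize("instructed", ["thumb", "index"])
    def test_error_probability_extremes(self, instructed):
        for seed in range(25):
            ok = generate_lever_traces(instructed, 0.0, seed)
            assert ok.success and classify_trial(ok)
            bad = generate_lever_traces(instructed, 1.0, seed)
            assert not bad.success and not classify_trial(bad)

    def test_error_probability_recovered_by_classifier(self):
        p = 0.2
        n = 10000
        rng = np.random.default_rng(42)
        failures = sum(
            not classify_trial(generate_lever_traces("thumb", p, rng)) for _ in range(n)
        )
        # binomial 99% interval around p
        half = 2.576 * np.sqrt(p * (1 - p) / n)
        assert abs(failures / n - p) < half


class TestRawTraces:
    def test_zero_rate_gives_pure_noise_and_is_deterministic(self):
        truth = UnitGroundTruth(baseline_rate=0.0)
        template = np.array([0.0, 10.0, 3.0, -2.0])
        t1, s1 = generate_raw_trace(truth, 1.0, template, 0.2, seed=5)
        t2, s2 = generate_raw_trace(truth, 1.0, template, 0.2, seed=5)
        assert s1.size == 0
        assert np.array_equal(t1, t2)
        assert abs(np.std(t1) - 1.0) < 0.05

    def test_templates_added_at_spike_times(self):
        truth = UnitGroundTruth(baseline_rate=50.0)
        template = np.array([0.0, 100.0, 0.0])
        trace, spikes = generate_raw_trace(truth, 0.01, template, 1.0, seed=3)
        fs = 25000.0
        for t in spikes:
            i = int(t * fs)
            assert trace[i + 1] > 50.0
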