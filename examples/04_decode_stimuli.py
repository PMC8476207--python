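"""Decode which nerve was stimulated from single-trial firing rates.

Converts each trial's spikes to a Gaussian-kernel instantaneous rate
(3-ms kernel on the PSTH grid) and classifies median vs ulnar trials with
leave-one-out LDA; also sweeps the kernel width to show why 3 ms is a good
operating point for stimulus-locked responses.
"""

import numpy as np

from pairedstim import ProtocolConfig, generate_session, kernel_sweep, loo_lda, rate_features
from pairedstim.histograms import PSTH_BIN_WIDTH, PSTH_WINDOW, per_trial_spikes
from pairedstim.synthetic import GaussComponent, UnitGroundTruth

# median and ulnar responses differ in latency (8 vs 12 ms)
truth = UnitGroundTruth(
    baseline_rate=15.0,
    stim_kernels={
        "median": (GaussComponent(0.008, 220.0, 0.0015, "early"),),
        "ulnar": (GaussComponent(0.012, 220.0, 0.0015, "early"),),
    },
)
archive = generate_session(ProtocolConfig(seed=5, nerve_assessment_count=150),
                           [truth], epochs=["nerve_before"])

trial_spikes, labels = [], []
for electrode in ("median", "ulnar"):
    events = archive.events("nerve_before", electrode)
    trial_spikes.extend(per_trial_spikes(
        archive.unit_spikes(0, "nerve_before"), events, PSTH_WINDOW))
    labels.extend([electrode] * len(events))

features = rate_features(trial_spikes, labels, window=PSTH_WINDOW,
                         bin_width=PSTH_BIN_WIDTH, kernel_width=0.003)
result = loo_lda(features)
print(f"median vs ulnar LOO-LDA accuracy (3-ms kernel): {result.accuracy:.3f}")

sweep = kernel_sweep(trial_spikes, labels, [0.001, 0.003, 0.010, 0.050],
                     window=PSTH_WINDOW, bin_width=PSTH_BIN_WIDTH)
for _, row in sweep.iterrows():
    print(f"  kernel {1000 * row['kernel_width']:5.0f} ms -> accuracy {row['accuracy']:.3f}")
# Accuracy peaks at a few milliseconds: narrower kernels replicate single
# spike timing noise, much wider kernels smear out the 4-ms latency
# difference between the two nerves.
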