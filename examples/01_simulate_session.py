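"""Simulate one experimental session and inspect its structure.

Builds a session archive with the six-epoch design (task and nerve
assessments bracketing paired median/ulnar stimulation), four synthetic
units, and saves it to disk in the CSV archive format.
"""

import numpy as np

from pairedstim import ProtocolConfig, generate_session, save_session
from pairedstim.synthetic import default_unit_truth

# scaled-down protocol so the example runs in seconds; drop the overrides
# to reproduce the full design (300 stimuli/electrode, ~1 h pairing,
# 150 trials/epoch)
protocol = ProtocolConfig(
    condition="synchronous",
    seed=1,
    nerve_assessment_count=100,
    paired_duration=120.0,
    task_trials_per_epoch=30,
)
rng = np.random.default_rng(0)
archive = generate_session(protocol, [default_unit_truth(rng) for _ in range(4)])

print(f"condition: {archive.condition}")
for epoch, (start, stop) in archive.epochs.items():
    n_events = (archive.stim_events["epoch"] == epoch).sum()
    n_trials = len(archive.epoch_trials(epoch))
    print(f"  {epoch:13s} {stop - start:7.0f} s  {n_events:5d} stimuli  {n_trials:3d} trials")
for u in range(len(archive.units)):
    total = sum(len(s) for s in archive.units[u].values())
    print(f"unit {u}: {total} spikes across the session")

save_session(archive, "scratch/example_session")
print("archive written to scratch/example_session/ "
      "(metadata.json, units.csv, events.csv, trials.csv, levers.csv)")
# The epoch table shows the experimental flow; spike totals reflect each
# unit's baseline rate plus its stimulus- and task-locked transients.
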