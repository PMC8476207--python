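"""Measure an injected plasticity effect with population Z-scores.

Simulates 25 units whose early response to median-nerve stimulation is
increased by 30% after the intervention, builds before/after PSTHs, and
aggregates bin-wise Z statistics across the population.  The EDC electrode
carries no plasticity and serves as the control.
"""

import numpy as np

from pairedstim import ProtocolConfig, build_psth, generate_session, z_population, z_stimulus
from pairedstim.synthetic import default_unit_truth

rng = np.random.default_rng(3)
truths = [
    default_unit_truth(rng, stim_plasticity={"median": {"early": 1.3}})
    for _ in range(25)
]
protocol = ProtocolConfig(seed=11, nerve_assessment_count=300)
archive = generate_session(protocol, truths, epochs=["nerve_before", "nerve_after1"])

for electrode in ("median", "EDC"):
    series = []
    for u in range(len(truths)):
        before = build_psth(archive.unit_spikes(u, "nerve_before"),
                            archive.events("nerve_before", electrode))
        after = build_psth(archive.unit_spikes(u, "nerve_after1"),
                           archive.events("nerve_after1", electrode))
        series.append(z_stimulus(before, after))
    pop = z_population(series)
    early = (pop.bin_starts >= 0.006) & (pop.bin_starts <= 0.012)
    n_sig = int(pop.sig_up[~pop.blanked].sum())
    print(f"{electrode:7s} mean Zbar in 6-12 ms: {pop.z[early].mean():6.2f}   "
          f"bins above +1.96: {n_sig}")
# The injected +30% early response pushes the median-nerve Zbar far above
# the 1.96 significance line in the early bins, while the unchanged EDC
# control hovers near zero with only chance-level flags.
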