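# Methods

This note documents the models, defaults and numerical choices behind
`pairedstim`, and what the synthetic-data validation does and does not
establish about real recordings.

## Session model

A session follows the six-epoch design: *task before*, *nerve before*,
*paired stimulation*, *nerve after 1*, *task after*, *nerve after 2*, laid
out sequentially with 10 s gaps. Nerve assessments deliver
`nerve_assessment_count` stimuli (default 300) per electrode — EDC, median,
ulnar — in randomized order at a fixed 500 ms interstimulus interval.
Paired stimulation runs for `paired_duration` (default 3,660 s) with
intervals drawn uniformly from 80–120 ms; in the synchronous condition the
ulnar pulse coincides with the median pulse, in the asynchronous condition
it falls at the midpoint of each interval. Task epochs hold
`task_trials_per_epoch` trials (default 150) at one trial per
`trial_interval` (default 8 s, matching a ~20 min epoch).

### Spike generation

Each unit's rate is

    r(t) = baseline + Σ_electrode Σ_components a·exp(−(t − t_event − ℓ)²/2σ²)
                    + Σ_trial-type Σ_components (same form around trial completion)

Stimulus kernels default to an early component (ℓ ≈ 9 ms, σ = 1.5 ms) and a
late component (ℓ ≈ 20 ms, σ = 4 ms), reflecting the short-latency
(~7–12 ms) and late (~12–30 ms) response epochs seen in motor cortex after
nerve stimulation; amplitudes default to ~90/45 spikes/s for median,
80% of that for ulnar and 25% for EDC, on a ~15 spikes/s baseline, with
±15–30% per-unit jitter available for heterogeneous populations. Exact
latency and width distributions per nerve are not constrained by data, so
these are configuration defaults, not assertions. Task profiles are broad
Gaussian bumps peaking before trial completion (thumb: −150 ms, σ 120 ms,
~30 spikes/s; index: −250 ms, σ 150 ms, ~70% of that).

Plasticity is multiplicative per component (`stim_plasticity[electrode][label]`)
and per trial type (`task_plasticity[type]`), applied only in the three
post-intervention epochs. Multiplicative effects were chosen because they
make parameter recovery well-posed (a ×1.2 multiplier has a predictable
Z̄ signature) while reproducing the qualitative phenomenology of interest —
early responses scaled up, late responses scaled down, task activity scaled
per trial type.

Sampling uses Poisson thinning with a per-epoch ceiling computed from the
components actually present in that epoch. Component support is truncated
at ±4σ (< 50 ms), which is shorter than the minimum event spacing (80 ms),
so only the immediately neighboring event per alignment stream can
contribute at any instant; this keeps rate evaluation O(log n) per
candidate. A configuration whose worst-case rate is negative (a suppressive
component deeper than baseline) is rejected at generation time. All
randomness derives from one seed through named substreams (`events`,
`levers`, `spikes-unit{i}`), so each component is independently
reproducible.

### Lever trajectories

The task is selective digit abduction: thumb-instructed trials succeed when
the thumb exceeds 7° while the index stays below 11°; index-instructed
trials when the index exceeds 8° and the thumb stays below 17°
(inequalities strict — the thresholds say "exceed" / "stay below", and the
boundary convention is documented here because the rules do not address
equality). Traces are minimum-jerk ramps to a peak plus smooth low-frequency
wobble (±0.2°); no empirical trajectory model is claimed. Peaks are drawn so
outcomes are exact by construction: with probability `error_probability`
(default 0.15 — a trained-monkey error rate) the noninstructed digit
crosses its maximal-motion threshold, which is the scored failure mode.
Because peak ranges clear the thresholds by more than the wobble amplitude,
`classify_trial` recovers the generated outcome exactly.

## Histograms, blanking, shuffle test

PSTH grid: [−20, +100) ms, 1 ms half-open bins `[t, t+Δ)`. Blanking sets to
zero the seven bins whose starts lie in 0…6 ms (the "0 ms before to 6 ms
after" artifact interval read as seven full bins — the endpoint phrasing is
ambiguous between 6 and 7 bins; the 7-bin reading is adopted and
configurable) plus the bin containing −10 ms, where relay switching ahead
of the stimulus can leave an artifact. PETH grid: [−500, +200) ms, 10 ms
bins, aligned to the completion of successful trials, no blanking. Rates
are count/(m·Δ) throughout.

The ISI-shuffle test permutes each trial's interspike-interval sequence
(preserving the first spike's latency from the window start and the
per-trial spike count), rebuilds the PETH per shuffle, and compares the
observed peak modulation (max − min bin rate) against the shuffled
distribution; a unit is significant when the observed value strictly
exceeds >95% of 1,000 shuffles. Ties count against significance
(conservative). Preserving the first-spike latency rather than the last, or
resampling offsets, are equally defensible conventions; this one is fixed
and tested. Trials with ≤1 spike pass through unchanged (no ISIs to
permute).

## Z statistics

Both Z formulas assume Poisson bin counts (variance = mean). The stimulus
variant subtracts each epoch's baseline rate, estimated from the baseline
bins of the same histogram; the baseline defaults to all unblanked
pre-stimulus bins (19 of the 20 bins in [−20, 0) ms after removing the
relay bin) since no separate quiet period is defined. The task variant uses
no baseline. Bins where every contributing count is zero have an undefined
Z; they are reported as Z = 0 with a `degenerate` flag rather than NaN so
population sums stay defined (at experimental rates such bins are rare and
the calibration tests account for them).

The population average divides by √N and the condition contrast by √2:
these are the unique normalizations that keep unit variance under the null,
which is the property the statistics are used for. Significance shading
uses ±1.96 (two-sided 95%).

Calibration (acceptance suite): over 10⁴ simulated null bin pairs at
m = 300 trials and rates spanning 1–100 spikes/s, both Z variants and the
50-unit Z̄ have mean within ±0.03 of 0 and SD within [0.95, 1.05]. At rates
near 1 spike/s the per-bin distribution is visibly discrete (many
zero/zero bins); the SD band already absorbs this.

## Decoding

Rate features: unit-area Gaussian kernel evaluated at bin centers,
truncated at ±4σ; no edge padding, so rates within ~4σ of the window edges
are biased low — accepted because both compared classes share the bias.
Kernel widths default to 3 ms (stimulus) and 190 ms (task), the plateau
points of the accuracy-vs-width sweep reproduced in
`examples/04_decode_stimuli.py` and the kernel-sweep tests.

The classifier is a two-class linear discriminant with pooled
(within-class) covariance, equal priors regardless of trial imbalance
(accuracies are compared against 50%), and shrinkage of the pooled
covariance toward its diagonal with fixed coefficient 0.1 — needed because
the feature count (120 columns on the PSTH grid) rivals the trial count. A
small relative ridge (1e−8 of the mean diagonal) guards exactly singular
cases such as all-zero feature columns. Discriminant ties (score exactly 0)
go to the lexicographically first class label, making degenerate inputs
deterministic. Features are used raw; a standardization switch is not
applied by default since the discriminant is affine-equivariant up to
shrinkage.

Leave-one-out refits are computed exactly via rank-one downdates of the
pooled scatter (each fold's covariance, diagonal target included, is the
full-data matrix minus one rank-one term), solved batched; equivalence to a
literal per-fold refit and to an external LDA implementation is unit-tested.
This is what makes the per-unit Monte Carlo test affordable.

The per-unit accuracy-change test is a permutation test: trials are pooled
across the two epochs and epoch labels reassigned at random *within each
class* (preserving both epoch sizes and class balance), the LOO accuracy
difference recomputed per permutation, and a two-sided p-value taken with
the add-one estimator. The within-class constraint keeps every permuted
pseudo-epoch a valid two-class problem. The default is 1,000 permutations;
the validation suite uses 99 (p resolution 0.01) where only α = 0.05
decisions are needed.

## Behavior and inference

A = c/(e+c) and s = c/t with t the epoch wall-clock duration in minutes
(task-engaged time is not separately tracked). Deltas are after − before,
so positive means improvement. Condition comparisons use a standard
fixed-effects two-way ANOVA (monkey × stimulation; statsmodels OLS with
type-2 sums of squares) plus one-sample and two-sample post hoc t tests,
all routed through Benjamini–Hochberg at q = 0.05 as one family per call.
Degenerate inputs (all deltas identical) short-circuit to F = 0, p = 1
rather than 0/0. An empty design cell drops the interaction with a warning.

Benjamini–Hochberg is the classic step-up rule (no adaptive null-proportion
estimation), delegated to statsmodels and property-tested against a
hand-rolled step-up oracle. The direction-proportion Monte Carlo test uses
a fair-coin null among the units that changed (ties fixed), two-sided on
the deviation from an even split; the null model is a fixed documented
choice. The instability control reports Pearson r² between per-unit firing
rate change and accuracy change, flagging zero-variance input as
degenerate.

## Problem sizes used in validation

The acceptance suite runs at the sizes its guarantees are stated for:
10⁴ null bin pairs (Z calibration), 1,000 units × 1,000 shuffles (shuffle
type-I error), 200 sessions × 200 trials (chance decoding), 10⁴ families
(FDR), 10⁶ samples (threshold constant). Parameter recovery uses 8
replicate experiments of 50 units (nerve epochs only — the other epochs do
not enter the stimulus Z) for the +20% early-response injection, and 10
units at 150 trials per class for the coding-degradation test. End-to-end
pipeline tests use scaled-down sessions (tens of trials, 150 stimuli per
electrode) chosen to exercise every stage rather than to maximize power;
the full-power claims live in the dedicated suites.

## What passing tests do and do not show

The generator produces Poisson spiking with smooth additive transients,
exact trial outcomes and stationary baselines. Real multiunit recordings
have refractoriness, bursting, slow nonstationarities, electrode drift and
correlated noise across units — none of which are modeled. Calibration
results (Z ~ N(0,1), shuffle-test type-I error ≈ 5%, chance decoding at
50%, FDR ≤ q) therefore establish the correctness of the statistics under
their own stated assumptions, and parameter-recovery results establish that
the pipeline detects effects of the injected form; they do not establish
robustness to non-Poisson features of real data. The instability-control
correlation is the in-pipeline guard for one such feature (electrode
drift).

## Known limitations

* The Poisson variance model is assumed, not tested, by the Z statistics;
  an empirical bootstrap variance would be an extension.
* The discriminant is linear by design; no nonlinear decoders.
* Kernel rate estimates are biased at window edges (no padding correction).
* The shuffle-test convention (first-spike latency preserved) and the
  proportion-test null (fair coin among changed units) are fixed documented
  choices among equally defensible alternatives.
* Single-unit isolation (cluster cutting) is out of scope; archives carry
  labeled units.
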