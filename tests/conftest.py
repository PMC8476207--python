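import numpy as np
import pytest

from pairedstim.synthetic import (
    GaussComponent,
    ProtocolConfig,
    UnitGroundTruth,
    default_unit_truth,
    generate_session,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_protocol(**overrides) -> ProtocolConfig:
    """A scaled-down protocol for fast end-to-end tests (the defaults of
    ProtocolConfig itself match the full experimental design)."""
    kwargs = dict(
        seed=7,
        nerve_assessment_count=60,
        paired_duration=40.0,
        task_trials_per_epoch=24,
        trial_interval=4.0,
    )
    kwargs.update(overrides)
    return ProtocolConfig(**kwargs)


@pytest.fixture(scope="session")
def small_session():
    rng = np.random.default_rng(99)
    truths = [default_unit_truth(rng) for _ in range(3)]
    return generate_session(small_protocol(), truths)


def flat_unit(baseline=20.0) -> UnitGroundTruth:
    """A unit with no stimulus or task modulation (homogeneous Poisson)."""
    return UnitGroundTruth(baseline_rate=baseline)


def single_kernel_unit(latency=0.009, amplitude=90.0, sigma=0.0015,
                       baseline=15.0, electrode="median", label="early",
                       multiplier=None) -> UnitGroundTruth:
    plasticity = {}
    if multiplier is not None:
        plasticity = {electrode: {label: multiplier}}
    return UnitGroundTruth(
        baseline_rate=baseline,
        stim_kernels={electrode: (GaussComponent(latency, amplitude, sigma, label),)},
        stim_plasticity=plasticity,
    )
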