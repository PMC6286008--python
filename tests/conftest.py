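"""Shared fixtures: deterministic synthetic signals and datasets."""

import numpy as np
import pytest

from regpoincare.records import Segment
from regpoincare.synthetic import SynthConfig, generate_dataset, generate_record


def noiseless_config(**overrides) -> SynthConfig:
    """A fully deterministic generator configuration (no stochastic terms)."""
    base = dict(
        noise_sd=0.0, period_jitter_sd=0.0, pulse_range_jitter_sd=0.0,
        drift_amplitude=0.0, regime="baseline", regime_modulation=0.0,
    )
    base.update(overrides)
    return SynthConfig(**base)


def sine_segment(period_samples: int = 250, n_cycles: int = 16,
                 amplitude: float = 1.0, fs: float = 250.0) -> Segment:
    n = period_samples * n_cycles
    t = np.arange(n)
    return Segment(
        samples=amplitude * np.sin(2 * np.pi * t / period_samples),
        sampling_rate=fs, label="unknown",
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The study-sized dataset: 29 apnea + 24 baseline segments of 16 s."""
    return generate_dataset(29, 24, 16.0, seed=7)


@pytest.fixture(scope="session")
def default_sweep(default_dataset):
    """Descriptor sweep of the study-sized dataset over lags 1..70."""
    from regpoincare.poincare import feature_sweep

    return feature_sweep(default_dataset, range(1, 71))


@pytest.fixture()
def periodic_record():
    """Strictly periodic 1.0 s pulse train at 250 Hz, 16 s."""
    return generate_record(noiseless_config(period_mean=1.0, seed=0))
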