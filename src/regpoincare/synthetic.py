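"""Synthetic REG signal generator.

Emulates the pulsatile cerebral bioimpedance waveforms of the study protocol:
~1 s-period pulses (0.99 ± 0.12 s between segments), per-pulse amplitude
ranges near 0.09–0.10 Ω, slow drift and additive sensor noise, in two regimes.
The ``apnea`` regime is made less regular than ``baseline`` in two ways,
both scaled by one knob (``regime_modulation``): a correlated (AR(1))
beat-to-beat modulation of pulse amplitude, and amplified
sample-level microvariability (the additive noise floor).  The second part
is what lowers the autocorrelation at small sample lags — beat-scale
modulation alone only adds low-frequency power — so it is what lets the
lagged Poincaré descriptors (SDratio, R, CCM) separate the regimes at
small lags.

Each beat is an asymmetric pulse: a fast half-cosine anacrotic rise over
``rise_fraction`` of the period followed by a slower exponential-shaped decay
back to the beat minimum.  The template is normalised to [0, 1] per beat, so
after scaling each beat's max−min equals its drawn pulse range exactly
(before drift and noise are added).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .records import RegRecord, Segment, segment_from_record

#: AR(1) coefficient of the correlated beat-to-beat modulation (apnea regime).
AR1_COEFF = 0.9

#: Rate constant of the exponential-shaped diastolic decay (dimensionless).
#: Chosen so the mean pulse height is ~0.4x the range, giving per-beat areas
#: of order 10 ohm*samples for 0.09-ohm, ~1-s pulses.
DECAY_RATE = 1.5

_TABLE_RANGE_DEFAULTS = {"apnea": 0.092, "baseline": 0.099, "unknown": 0.095}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic REG record.

    Amplitudes are in ohms, times in seconds.  ``period_sd`` and
    ``pulse_range_sd`` are *between-segment* spreads used when drawing
    per-segment configurations for a dataset; the ``*_jitter_sd`` fields are
    the i.i.d. beat-to-beat spreads within one record.
    ``regime_modulation`` is the relative strength of the apnea-regime
    irregularity: the correlated AR(1) beat-to-beat amplitude modulation and
    the noise-floor amplification (0 disables both; the knob has no effect
    in the baseline regime).
    """

    sampling_rate: float = 250.0
    duration: float = 16.0
    period_mean: float = 0.99
    period_sd: float = 0.12
    period_jitter_sd: float = 0.02
    pulse_range_mean: float | None = None  # per-regime Table defaults if None
    pulse_range_sd: float = 0.03
    pulse_range_jitter_sd: float = 0.003
    rise_fraction: float = 0.21
    regime: str = "baseline"
    regime_modulation: float = 0.35
    drift_amplitude: float = 0.005
    drift_frequency: float = 0.05
    noise_sd: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if self.period_mean <= 0:
            raise ConfigurationError("period_mean must be positive")
        if not 0.0 < self.rise_fraction < 1.0:
            raise ConfigurationError("rise_fraction must lie in (0, 1)")
        if self.regime not in ("apnea", "baseline", "unknown"):
            raise ConfigurationError(f"unknown regime {self.regime!r}")
        for name in ("period_sd", "period_jitter_sd", "pulse_range_sd",
                     "pulse_range_jitter_sd", "noise_sd", "drift_amplitude",
                     "regime_modulation"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.drift_frequency < 0 or self.drift_frequency >= 0.1:
            raise ConfigurationError("drift_frequency must lie in [0, 0.1) Hz")

    @property
    def resolved_pulse_range_mean(self) -> float:
        if self.pulse_range_mean is not None:
            return self.pulse_range_mean
        return _TABLE_RANGE_DEFAULTS[self.regime]

    def digest(self) -> str:
        """Short hash of the configuration, recorded as provenance."""
        payload = repr(sorted(self.__dict__.items())).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


def _pulse_template(n: int, n_rise: int) -> np.ndarray:
    """One beat, ``n`` samples, normalised so min = 0 and max = 1 exactly.

    Half-cosine rise over samples [0, n_rise], exponential-shaped decay
    reaching 0 exactly at the last sample (continuity with the next beat).
    """
    n_rise = int(np.clip(n_rise, 1, n - 2))
    k = np.arange(n, dtype=float)
    out = np.empty(n)
    out[: n_rise + 1] = 0.5 * (1.0 - np.cos(np.pi * k[: n_rise + 1] / n_rise))
    u = (k[n_rise + 1 :] - n_rise) / (n - 1 - n_rise)
    e0 = np.exp(-DECAY_RATE)
    out[n_rise + 1 :] = (np.exp(-DECAY_RATE * u) - e0) / (1.0 - e0)
    return out


def _ar1_series(rng: np.random.Generator, n: int, coeff: float = AR1_COEFF) -> np.ndarray:
    """Stationary unit-variance AR(1) series of length n."""
    innov_sd = np.sqrt(1.0 - coeff**2)
    z = np.empty(n)
    z[0] = rng.normal()
    for i in range(1, n):
        z[i] = coeff * z[i - 1] + innov_sd * rng.normal()
    return z


def generate_record(config: SynthConfig) -> RegRecord:
    """Generate one synthetic REG record; deterministic given ``config.seed``."""
    fs = config.sampling_rate
    n_total = int(round(config.duration * fs))
    if n_total < 2:
        raise ConfigurationError("duration too short for the sampling rate")
    rng = np.random.default_rng(config.seed)

    # Draw enough beats to cover the record with margin.
    n_beats = int(np.ceil(config.duration / (0.4 * config.period_mean))) + 4
    periods = config.period_mean + rng.normal(0.0, config.period_jitter_sd, n_beats)
    ranges = config.resolved_pulse_range_mean + rng.normal(
        0.0, config.pulse_range_jitter_sd, n_beats
    )
    if config.regime == "apnea" and config.regime_modulation > 0:
        # Correlated amplitude modulation only: breath holding drives cerebral
        # blood volume (hence pulse amplitude) more than cardiac period on
        # 16-s windows, and period coupling re-creates spurious group
        # differences at lags near a quarter period.
        z = _ar1_series(rng, n_beats)
        ranges = ranges * (1.0 + config.regime_modulation * z)
    periods = np.clip(periods, 0.3 * config.period_mean, 3.0 * config.period_mean)
    ranges = np.clip(ranges, 0.05 * config.resolved_pulse_range_mean, None)

    # Beat boundaries on the sample grid (cumulative, so no rounding drift).
    starts = np.round(np.concatenate(([0.0], np.cumsum(periods))) * fs).astype(int)
    pieces = []
    for i in range(n_beats):
        beat_len = starts[i + 1] - starts[i]
        if beat_len < 4:
            continue
        n_rise = int(round(config.rise_fraction * beat_len))
        pieces.append(ranges[i] * _pulse_template(beat_len, n_rise))
        if starts[i + 1] >= n_total:
            break
    wave = np.concatenate(pieces)[:n_total]
    if wave.size < n_total:  # pad defensively (clipped-period edge case)
        wave = np.pad(wave, (0, n_total - wave.size), mode="edge")

    t = np.arange(n_total) / fs
    if config.drift_amplitude > 0 and config.drift_frequency > 0:
        wave = wave + config.drift_amplitude * np.sin(
            2.0 * np.pi * config.drift_frequency * t
        )
    noise_sd = config.noise_sd
    if config.regime == "apnea":
        # Apnea microvariability: the noise floor grows with the modulation
        # strength; this is the component that decorrelates small lags.
        noise_sd = noise_sd * (1.0 + 2.0 * config.regime_modulation)
    if noise_sd > 0:
        wave = wave + rng.normal(0.0, noise_sd, n_total)

    return RegRecord(
        samples=wave,
        sampling_rate=fs,
        regime_label=config.regime,
        meta={"config_digest": config.digest(), "seed": config.seed,
              "generator": "regpoincare.synthetic"},
    )


def generate_dataset(
    n_apnea: int,
    n_baseline: int,
    segment_length: float = 16.0,
    base_config: SynthConfig | None = None,
    seed: int = 0,
) -> list[Segment]:
    """Generate a labelled dataset of fixed-length segments.

    Defaults mirror the study protocol: 29 apnea + 24 baseline segments of
    16 s at 250 Hz.  Each segment comes from its own record whose mean period
    and pulse range are drawn from the between-segment distributions
    (``period_sd``, ``pulse_range_sd``); everything is reproducible from
    ``seed``.
    """
    if n_apnea < 0 or n_baseline < 0:
        raise ConfigurationError("segment counts must be non-negative")
    base = base_config if base_config is not None else SynthConfig()
    master = np.random.default_rng(seed)
    segments: list[Segment] = []
    labels = ["apnea"] * n_apnea + ["baseline"] * n_baseline
    for regime in labels:
        seg_period = max(
            0.3 * base.period_mean,
            master.normal(base.period_mean, base.period_sd),
        )
        regime_mean = (
            base.pulse_range_mean
            if base.pulse_range_mean is not None
            else _TABLE_RANGE_DEFAULTS[regime]
        )
        seg_range = max(
            0.05 * regime_mean, master.normal(regime_mean, base.pulse_range_sd)
        )
        cfg = replace(
            base,
            regime=regime,
            duration=segment_length,
            period_mean=seg_period,
            pulse_range_mean=seg_range,
            seed=int(master.integers(0, 2**31 - 1)),
        )
        record = generate_record(cfg)
        segments.append(
            segment_from_record(record, 0, int(round(segment_length * cfg.sampling_rate)))
        )
    return segments
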