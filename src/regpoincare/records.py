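"""Core containers for REG signals.

A :class:`RegRecord` is a raw (or filtered) single-channel rheoencephalographic
bioimpedance trace: samples in ohms at a fixed sampling rate, tagged with the
recording regime (breath-holding ``apnea`` vs resting ``baseline``).  A
:class:`Segment` is a fixed-length artifact-free excerpt of a record, the unit
on which all descriptors are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from .errors import ConfigurationError

REGIMES = ("apnea", "baseline", "unknown")


def _as_valid_samples(samples: Any) -> np.ndarray:
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 1:
        raise ConfigurationError(f"samples must be 1-D, got shape {arr.shape}")
    if arr.size < 2:
        raise ConfigurationError("a signal needs at least 2 samples")
    if not np.all(np.isfinite(arr)):
        raise ConfigurationError("samples must be finite")
    return arr


@dataclass(frozen=True)
class RegRecord:
    """A sampled REG signal in ohms.

    Parameters
    ----------
    samples : array-like
        Bioimpedance samples, ohms.
    sampling_rate : float
        Sampling rate in Hz (250 Hz for the emulated recordings).
    regime_label : str
        ``"apnea"``, ``"baseline"`` or ``"unknown"``.
    meta : mapping
        Free-form provenance (generator config, seed, filter history).
    """

    samples: np.ndarray
    sampling_rate: float
    regime_label: str = "unknown"
    meta: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", _as_valid_samples(self.samples))
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.regime_label not in REGIMES:
            raise ConfigurationError(
                f"regime_label must be one of {REGIMES}, got {self.regime_label!r}"
            )

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class Segment:
    """A fixed-length artifact-free excerpt of a :class:`RegRecord`."""

    samples: np.ndarray
    sampling_rate: float
    label: str = "unknown"
    source_offset: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", _as_valid_samples(self.samples))
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.label not in REGIMES:
            raise ConfigurationError(
                f"label must be one of {REGIMES}, got {self.label!r}"
            )
        if self.source_offset < 0:
            raise ConfigurationError("source_offset must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


def write_csv(obj: RegRecord | Segment, path: str | Path) -> None:
    """Write a record or segment as plain CSV.

    Header comment lines carry the sampling rate and label
    (``# fs_hz=250``, ``# label=apnea``), then one sample (ohms) per row.
    """
    label = obj.regime_label if isinstance(obj, RegRecord) else obj.label
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs_hz={obj.sampling_rate:g}\n")
        fh.write(f"# label={label}\n")
        for v in obj.samples:
            fh.write(f"{v:.9g}\n")


def read_csv(path: str | Path) -> RegRecord:
    """Read the CSV dialect written by :func:`write_csv`."""
    path = Path(path)
    fs: float | None = None
    label = "unknown"
    values: list[float] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                key = key.strip()
                val = val.strip()
                if key == "fs_hz":
                    fs = float(val)
                elif key == "label":
                    label = val
                continue
            values.append(float(line))
    if fs is None:
        raise ConfigurationError(f"{path}: missing '# fs_hz=' header")
    return RegRecord(
        samples=np.asarray(values), sampling_rate=fs, regime_label=label,
        meta={"source": str(path)},
    )


def segment_from_record(record: RegRecord, start: int, n_samples: int) -> Segment:
    """Cut ``n_samples`` starting at ``start`` out of a record."""
    if start < 0 or start + n_samples > record.n_samples:
        raise ConfigurationError("segment window exceeds record bounds")
    return Segment(
        samples=record.samples[start : start + n_samples].copy(),
        sampling_rate=record.sampling_rate,
        label=record.regime_label,
        source_offset=start,
    )
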