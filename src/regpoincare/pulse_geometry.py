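"""Per-pulse landmark detection and classical time-domain features.

For each beat (minimum-to-minimum), ten descriptors are computed and then
summarised per segment by the median, to match the robustness convention of
classical REG pulse-wave analysis: signed maximum and minimum amplitudes,
amplitude range, consecutive-maximum and consecutive-minimum spacings, the
minimum-to-following-maximum spacing (anacrotic rise time), the rise slope
alpha = range / rise-time, the area under the pulse above its own minimum,
and the maximum and range of the per-sample forward difference.

Spacings are expressed in samples, the slope in ohm/sample, derivatives in
ohm/sample, and the area in ohm*samples (trapezoidal rule over one beat).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import signal

from .errors import InsufficientDataError, InsufficientPulsesError
from .records import Segment

#: Minimum inter-peak distance, seconds (equivalent to a 150 bpm ceiling).
MIN_PEAK_SPACING_S = 0.4

FEATURE_COLUMNS = ["Max", "Min", "Range", "dt_max", "dt_min", "dt_min_max",
                   "alpha", "Area", "d_max", "d_range"]


@dataclass(frozen=True)
class PulseLandmarks:
    """Alternating per-beat minima and maxima (sample indices)."""

    minima: np.ndarray
    maxima: np.ndarray

    def __post_init__(self) -> None:
        mins = np.asarray(self.minima, dtype=int)
        maxs = np.asarray(self.maxima, dtype=int)
        object.__setattr__(self, "minima", mins)
        object.__setattr__(self, "maxima", maxs)
        merged = np.sort(np.concatenate([mins, maxs]))
        if np.any(np.diff(merged) <= 0):
            raise ValueError("landmark indices must be strictly increasing")

    @property
    def n_pulses(self) -> int:
        """Complete pulses: min -> max -> next min triples."""
        count = 0
        for i in range(len(self.minima) - 1):
            lo, hi = self.minima[i], self.minima[i + 1]
            if np.any((self.maxima > lo) & (self.maxima < hi)):
                count += 1
        return count


@dataclass(frozen=True)
class GeometryFeatures:
    """Median-over-pulses time-domain descriptors of one segment."""

    max_amp: float      # ohm
    min_amp: float      # ohm
    range_amp: float    # ohm
    dt_max: float       # samples
    dt_min: float       # samples
    dt_min_max: float   # samples
    alpha: float        # ohm / sample
    area: float         # ohm * samples
    deriv_max: float    # ohm / sample
    deriv_range: float  # ohm / sample

    def as_series(self) -> pd.Series:
        return pd.Series(
            [getattr(self, f.name) for f in fields(self)], index=FEATURE_COLUMNS
        )


def _enforce_alternation(
    x: np.ndarray, minima: np.ndarray, maxima: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Keep the most extreme candidate between consecutive opposite landmarks."""
    events = sorted(
        [(i, -1) for i in minima] + [(i, +1) for i in maxima], key=lambda e: e[0]
    )
    kept: list[tuple[int, int]] = []
    for idx, kind in events:
        if kept and kept[-1][1] == kind:
            prev_idx, _ = kept[-1]
            better = (x[idx] > x[prev_idx]) if kind == +1 else (x[idx] < x[prev_idx])
            if better:
                kept[-1] = (idx, kind)
        else:
            kept.append((idx, kind))
    mins = np.array([i for i, k in kept if k == -1], dtype=int)
    maxs = np.array([i for i, k in kept if k == +1], dtype=int)
    return mins, maxs


def detect_landmarks(segment: Segment) -> PulseLandmarks:
    """Detect per-beat minima and maxima of a band-limited segment.

    Local-extremum search with a minimum spacing of 0.4 s between same-kind
    landmarks; alternation is enforced by keeping the most extreme candidate
    between consecutive opposite landmarks.
    """
    x = segment.samples
    distance = max(1, int(round(MIN_PEAK_SPACING_S * segment.sampling_rate)))
    # Prominence floor keeps noise wiggles on the diastolic decay from
    # masquerading as beats; 25% of the robust amplitude span.
    span = float(np.percentile(x, 97.5) - np.percentile(x, 2.5))
    prominence = 0.25 * span if span > 0 else None
    maxima, _ = signal.find_peaks(x, distance=distance, prominence=prominence)
    minima, _ = signal.find_peaks(-x, distance=distance, prominence=prominence)
    if maxima.size and minima.size:
        minima, maxima = _enforce_alternation(x, minima, maxima)
    lm = PulseLandmarks(minima=minima, maxima=maxima)
    if lm.n_pulses < 3:
        raise InsufficientPulsesError(
            f"found {lm.n_pulses} complete pulses; need at least 3"
        )
    return lm


def compute_geometry(segment: Segment, landmarks: PulseLandmarks) -> GeometryFeatures:
    """Compute the ten per-pulse descriptors, medianed over pulses."""
    x = segment.samples
    mins, maxs = landmarks.minima, landmarks.maxima

    max_v, min_v, rng_v, dt_mm, alpha_v = [], [], [], [], []
    area_v, dmax_v, drange_v = [], [], []
    for i in range(len(mins) - 1):
        lo, hi = mins[i], mins[i + 1]
        between = maxs[(maxs > lo) & (maxs < hi)]
        if between.size == 0:
            continue
        pk = int(between[0])
        beat = x[lo : hi + 1]
        max_v.append(x[pk])
        min_v.append(min(x[lo], x[hi]))
        rng_v.append(x[pk] - min(x[lo], x[hi]))
        dt_mm.append(pk - lo)
        alpha_v.append((x[pk] - min(x[lo], x[hi])) / (pk - lo))
        area_v.append(np.trapezoid(beat - beat.min()))
        d = np.diff(beat)
        dmax_v.append(d.max())
        drange_v.append(d.max() - d.min())
    if len(rng_v) < 3:
        raise InsufficientPulsesError("fewer than 3 complete pulses")

    return GeometryFeatures(
        max_amp=float(np.median(max_v)),
        min_amp=float(np.median(min_v)),
        range_amp=float(np.median(rng_v)),
        dt_max=float(np.median(np.diff(maxs))),
        dt_min=float(np.median(np.diff(mins))),
        dt_min_max=float(np.median(dt_mm)),
        alpha=float(np.median(alpha_v)),
        area=float(np.median(area_v)),
        deriv_max=float(np.median(dmax_v)),
        deriv_range=float(np.median(drange_v)),
    )


def geometry_table(segments: list[Segment]) -> pd.DataFrame:
    """One row of geometry features (plus label) per segment."""
    rows = []
    for k, seg in enumerate(segments):
        feats = compute_geometry(seg, detect_landmarks(seg))
        row = feats.as_series()
        row["label"] = seg.label
        row["segment_id"] = k
        rows.append(row)
    return pd.DataFrame(rows).reset_index(drop=True)


def compare_geometry(
    features_apnea: list[GeometryFeatures],
    features_baseline: list[GeometryFeatures],
) -> pd.DataFrame:
    """Per-feature group means, SDs and a two-sample p-value.

    Uses the normality-gated test (Welch t vs Mann-Whitney, Lilliefors
    screen) of :mod:`regpoincare.group_stats`.
    """
    from .group_stats import compare_groups

    if len(features_apnea) < 2 or len(features_baseline) < 2:
        raise InsufficientDataError("need at least 2 segments per group")
    a = pd.DataFrame([f.as_series() for f in features_apnea])
    b = pd.DataFrame([f.as_series() for f in features_baseline])
    rows = []
    for col in FEATURE_COLUMNS:
        cmp = compare_groups(a[col].to_numpy(), b[col].to_numpy())
        rows.append({
            "feature": col,
            "apnea_mean": a[col].mean(), "apnea_sd": a[col].std(),
            "baseline_mean": b[col].mean(), "baseline_sd": b[col].std(),
            "p_value": cmp.p_value, "test": cmp.test_used,
        })
    return pd.DataFrame(rows)
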