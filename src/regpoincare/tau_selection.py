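"""Embedding-lag (tau) selection criteria.

Implements the classical recipes for choosing the delay of a Poincaré plot /
2-D delay embedding — fractions of the dominant cycle period, the first
local minimum of the auto-mutual information function (AMIF), and four
autocorrelation-based rules (first zero crossing, 1/e decay, first sign
change of the second derivative, fractions of the lag of the first local
minimum) — plus the CCM-inflection rule: the knee where the CCM-vs-tau
curve stops decreasing and plateaus, read as the point where the signal and
its delayed copy lose correlation.

All lags are in samples.  The ACF uses the biased (divide-by-n) estimator,
which keeps |rho| <= 1 and the sequence positive semidefinite.  The AMIF is
estimated from a 16x16 equal-width joint histogram; values are in nats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import CriterionNotFoundError, NoPeriodError
from .records import Segment

#: Physiological band for the dominant pulse period: 30-180 bpm.
PERIOD_BAND_S = (0.33, 2.0)

#: Minimum in-band ACF peak height to accept a dominant period.
PERIOD_MIN_RHO = 0.1

AMIF_BINS = 16


@dataclass(frozen=True)
class TauCriteria:
    """Per-segment lag recommendations (samples)."""

    quarter_period: float
    fifth_period: float
    amif_first_min: float | None
    acf_first_zero: float | None
    acf_1_over_e: float | None
    acf_second_deriv_sign_change: float | None
    acf_first_min_over_10: float | None
    acf_first_min_over_20: float | None
    ccm_inflection: float | None = None

    def as_series(self) -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name) for f in fields(self)})


class AcfCriteria(NamedTuple):
    first_zero: int | None
    one_over_e: int | None
    second_deriv_sign_change: int | None
    first_local_min: int | None


def autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased normalised ACF rho(0..max_lag), rho(0) = 1."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0.0:
        raise CriterionNotFoundError("constant series has no ACF")
    full = np.correlate(xc, xc, mode="full")[n - 1 : n + max_lag]
    return full / denom


def dominant_period(segment: Segment) -> int:
    """Dominant pulse period in samples.

    Lag of the highest ACF peak within the physiological band 0.33-2.0 s;
    the peak must be a local maximum with rho above ``PERIOD_MIN_RHO``.
    """
    fs = segment.sampling_rate
    lo = int(round(PERIOD_BAND_S[0] * fs))
    hi = int(round(PERIOD_BAND_S[1] * fs))
    hi = min(hi, segment.n_samples // 2)
    if hi - lo < 2:
        raise NoPeriodError("segment too short for the period band")
    rho = autocorrelation(segment.samples, hi + 1)
    band = rho[lo : hi + 1]
    k = int(np.argmax(band)) + lo
    is_local_peak = (0 < k < hi) and rho[k] >= rho[k - 1] and rho[k] >= rho[k + 1]
    if rho[k] < PERIOD_MIN_RHO or not is_local_peak:
        raise NoPeriodError(
            f"no ACF peak above {PERIOD_MIN_RHO} in the {PERIOD_BAND_S} s band"
        )
    return k


def acf_criteria(segment: Segment, max_lag: int) -> AcfCriteria:
    """Four ACF-based lag criteria; unreached criteria are ``None``.

    first_zero: smallest lag with rho <= 0.  one_over_e: smallest lag with
    rho <= 1/e.  second_deriv_sign_change: first sign change of the central
    second difference of rho.  first_local_min: smallest lag that is a
    strict local minimum of rho.
    """
    if max_lag >= segment.n_samples // 2:
        raise CriterionNotFoundError("max_lag must be below half the segment length")
    rho = autocorrelation(segment.samples, max_lag + 1)

    nonpos = np.nonzero(rho[1 : max_lag + 1] <= 0.0)[0]
    first_zero = int(nonpos[0]) + 1 if nonpos.size else None

    below = np.nonzero(rho[1 : max_lag + 1] <= 1.0 / math.e)[0]
    one_over_e = int(below[0]) + 1 if below.size else None

    d2 = rho[2:] - 2.0 * rho[1:-1] + rho[:-2]  # index k -> lag k+1
    # Scan from lag 2: the central difference at lag 1 involves rho(0),
    # which carries the white-noise spike and would trigger a spurious flip.
    sign_change = None
    signs = np.sign(d2[1:])  # index k -> lag k+2
    nz = np.nonzero(signs)[0]
    if nz.size:
        s0 = signs[nz[0]]
        flips = np.nonzero((signs != 0) & (signs != s0))[0]
        if flips.size:
            sign_change = int(flips[0]) + 2

    # Start at lag 2 for the same reason: the test at lag 1 compares
    # against rho(0) = 1, which carries the noise spike.
    first_local_min = None
    for k in range(2, max_lag):
        if rho[k - 1] > rho[k] < rho[k + 1]:
            first_local_min = k
            break

    return AcfCriteria(first_zero, one_over_e, sign_change, first_local_min)


def _mutual_information(x: np.ndarray, y: np.ndarray, bins: int = AMIF_BINS) -> float:
    """Plug-in MI (nats) from an equal-width 2-D histogram."""
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / (px @ py)[mask])))


def amif(segment: Segment, max_lag: int) -> np.ndarray:
    """Auto-mutual information I(0..max_lag), nats."""
    x = segment.samples
    out = np.empty(max_lag + 1)
    out[0] = _mutual_information(x, x)
    for tau in range(1, max_lag + 1):
        out[tau] = _mutual_information(x[:-tau], x[tau:])
    return out


def amif_first_min(segment: Segment, max_lag: int, smooth_window: int = 5) -> int:
    """Lag of the first local minimum of the (lightly smoothed) AMIF.

    The binned plug-in AMIF is jagged — quantisation of a near-deterministic
    signal produces fine structure on top of the information decay — so the
    curve is smoothed with a centred ``smooth_window``-point moving average
    before the first strict local minimum is taken.
    """
    curve = amif(segment, max_lag)
    smoothed = (
        pd.Series(curve).rolling(smooth_window, center=True, min_periods=1)
        .mean().to_numpy()
    )
    for k in range(1, max_lag):
        if smoothed[k - 1] > smoothed[k] < smoothed[k + 1]:
            return k
    raise CriterionNotFoundError(f"no AMIF local minimum within lag {max_lag}")


def segment_criteria(segment: Segment, max_lag: int | None = None) -> TauCriteria:
    """All criteria for one segment (missing entries are ``None``)."""
    period = dominant_period(segment)
    if max_lag is None:
        max_lag = min(2 * period, segment.n_samples // 2 - 1)
    acf = acf_criteria(segment, max_lag)
    try:
        amif_min: int | None = amif_first_min(segment, max_lag)
    except CriterionNotFoundError:
        amif_min = None
    flm = acf.first_local_min
    return TauCriteria(
        quarter_period=period / 4.0,
        fifth_period=period / 5.0,
        amif_first_min=amif_min,
        acf_first_zero=acf.first_zero,
        acf_1_over_e=acf.one_over_e,
        acf_second_deriv_sign_change=acf.second_deriv_sign_change,
        acf_first_min_over_10=None if flm is None else flm / 10.0,
        acf_first_min_over_20=None if flm is None else flm / 20.0,
    )


def criteria_table(
    segments: Sequence[Segment], max_lag: int | None = None
) -> pd.DataFrame:
    """Aggregate the criteria over segments, Table-2 style.

    Criteria are columns; rows are mean, std, min, max; missing per-segment
    values are skipped.  The attribute ``df.attrs['recommended_max_tau']``
    holds the sweep upper bound: the ceiling of the largest criterion mean.
    """
    if not segments:
        raise CriterionNotFoundError("need at least one segment")
    per_seg = pd.DataFrame([segment_criteria(s, max_lag).as_series() for s in segments])
    per_seg = per_seg.drop(columns=["ccm_inflection"])
    table = pd.DataFrame({
        "mean": per_seg.mean(), "std": per_seg.std(),
        "min": per_seg.min(), "max": per_seg.max(),
    }).T
    means = table.loc["mean"].dropna()
    table.attrs["recommended_max_tau"] = (
        int(math.ceil(means.max())) if not means.empty else None
    )
    table.attrs["all_missing"] = [c for c in per_seg.columns if per_seg[c].isna().all()]
    return table


def ccm_inflection(
    ccm_curve: Sequence[float],
    taus: Sequence[int] | None = None,
    smooth_window: int = 5,
    plateau_fraction: float = 0.05,
) -> int:
    """Knee of the CCM-vs-tau curve: where decrease gives way to plateau.

    The curve is smoothed with a centred moving average (``smooth_window``
    points), the centred first difference is taken, and the knee is the
    smallest tau at which that difference rises above ``plateau_fraction``
    times the initial mean slope (the mean difference over the first three
    lags).  A curve that never flattens, or that does not start by
    decreasing, has no knee.
    """
    curve = np.asarray(ccm_curve, dtype=float)
    if curve.size < 10:
        raise CriterionNotFoundError("need a CCM curve over at least 10 lags")
    taus_arr = np.arange(1, curve.size + 1) if taus is None else np.asarray(taus, int)
    if taus_arr.size != curve.size or np.any(np.diff(taus_arr) != 1):
        raise CriterionNotFoundError("taus must be contiguous and match the curve")

    smoothed = (
        pd.Series(curve).rolling(smooth_window, center=True, min_periods=1).mean().to_numpy()
    )
    diff = np.empty_like(smoothed)
    diff[1:-1] = (smoothed[2:] - smoothed[:-2]) / 2.0
    diff[0] = smoothed[1] - smoothed[0]
    diff[-1] = smoothed[-1] - smoothed[-2]

    head = diff[taus_arr <= taus_arr[0] + 2]
    initial_slope = float(head.mean())
    if initial_slope >= 0.0:
        raise CriterionNotFoundError("CCM curve does not start by decreasing")
    threshold = plateau_fraction * initial_slope  # negative, near zero
    for i in range(head.size, curve.size):
        if diff[i] > threshold:
            # The moving average smears the transition by ~half a window;
            # compensate so the knee lands where the raw curve flattens.
            knee = int(taus_arr[i]) - smooth_window // 2
            return max(knee, int(taus_arr[0]))
    raise CriterionNotFoundError("CCM curve decreases without reaching a plateau")
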