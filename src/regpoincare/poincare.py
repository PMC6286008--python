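"""Lagged Poincaré-plot descriptors: SD1, SD2, SDarea, SDratio, R and CCM.

A Poincaré plot is the two-dimensional delay embedding of a series x:
points (x(t), x(t+tau)) for t = 0 .. N-tau-1.  SD1 and SD2 are the standard
deviations along the axes perpendicular and parallel to the identity line,
i.e. of (x-y)/sqrt(2) and (x+y)/sqrt(2); SDarea = pi*SD1*SD2 is the fitted
ellipse area and SDratio = SD1/SD2 a dimensionless regularity index.  R is
the Pearson correlation between the signal and its lagged copy.  The Complex
Correlation Measure (CCM) is the mean unsigned area of the triangles formed
by all consecutive point triplets of the plot, normalised by the ellipse
area, and so captures temporal ordering that the variance descriptors
ignore.

Sample statistics use the n-1 denominator throughout.  Triangle area is
|determinant|/2 (the standard geometric convention); the normalising count
is the number of triplets, n_points - 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegeneratePlotError, LagError
from .records import Segment

logger = logging.getLogger(__name__)

POINCARE_FEATURES = ["SD1", "SD2", "SDarea", "SDratio", "R", "CCM"]


@dataclass(frozen=True)
class PoincarePlot:
    """Delay-embedded point cloud (x(t), x(t+tau))."""

    x: np.ndarray
    y: np.ndarray
    tau: int

    @property
    def n_points(self) -> int:
        return int(self.x.size)


@dataclass(frozen=True)
class PoincareFeatures:
    """All six descriptors of one segment at one lag."""

    sd1: float
    sd2: float
    sd_area: float
    sd_ratio: float
    r: float
    ccm: float
    tau: int


def embed(segment: Segment | np.ndarray, tau: int) -> PoincarePlot:
    """Embed a series (or segment) at lag ``tau`` samples.

    Valid lags satisfy 1 <= tau <= N-3 so the plot keeps at least 3 points.
    """
    samples = segment.samples if isinstance(segment, Segment) else np.asarray(segment, float)
    n = samples.size
    if not 1 <= tau <= n - 3:
        raise LagError(f"tau={tau} outside [1, {n - 3}] for series of length {n}")
    return PoincarePlot(x=samples[: n - tau], y=samples[tau:], tau=int(tau))


def sd_descriptors(plot: PoincarePlot) -> tuple[float, float, float]:
    """(SD1, SD2, SDarea) of a plot; well defined even when degenerate."""
    if plot.n_points < 2:
        raise DegeneratePlotError("need at least 2 points")
    d = (plot.x - plot.y) / np.sqrt(2.0)
    s = (plot.x + plot.y) / np.sqrt(2.0)
    sd1 = float(np.std(d, ddof=1))
    sd2 = float(np.std(s, ddof=1))
    return sd1, sd2, float(np.pi * sd1 * sd2)


def sd_features(plot: PoincarePlot) -> tuple[float, float, float, float]:
    """(SD1, SD2, SDarea, SDratio) of a plot.

    SD1 = std((x-y)/sqrt2), SD2 = std((x+y)/sqrt2) with the n-1 denominator.
    A constant x+y (SD2 = 0) makes the ratio undefined and raises
    :class:`DegeneratePlotError`.
    """
    sd1, sd2, sd_area = sd_descriptors(plot)
    if sd2 == 0.0:
        raise DegeneratePlotError("SD2 = 0: SDratio undefined")
    return sd1, sd2, sd_area, sd1 / sd2


def correlation_r(plot: PoincarePlot) -> float:
    """Pearson correlation between the signal and its lagged copy.

    Each window uses its own mean and variance (plain product-moment
    correlation on (x, y)); the difference from using one global mean is
    O(tau/N).
    """
    x, y = plot.x, plot.y
    vx = np.var(x, ddof=1)
    vy = np.var(y, ddof=1)
    if vx == 0.0 or vy == 0.0:
        raise DegeneratePlotError("zero variance: correlation undefined")
    cov = float(np.mean((x - x.mean()) * (y - y.mean())) * x.size / (x.size - 1))
    return float(np.clip(cov / np.sqrt(vx * vy), -1.0, 1.0))


def triangle_areas(plot: PoincarePlot) -> np.ndarray:
    """Unsigned areas of all consecutive point triplets (vectorised)."""
    x, y = plot.x, plot.y
    x0, x1, x2 = x[:-2], x[1:-1], x[2:]
    y0, y1, y2 = y[:-2], y[1:-1], y[2:]
    det = x0 * (y1 - y2) + x1 * (y2 - y0) + x2 * (y0 - y1)
    return 0.5 * np.abs(det)


def ccm(segment: Segment | np.ndarray, tau: int) -> float:
    """Complex Correlation Measure at lag ``tau``.

    Mean triangle area over the n_points-2 consecutive triplets, normalised
    by the ellipse area pi*SD1*SD2.  Collinear triplets contribute zero.
    Invariant to affine amplitude transforms of the series.
    """
    plot = embed(segment, tau)
    if plot.n_points < 3:
        raise LagError("need at least 3 plot points for CCM")
    sd1, sd2, sd_area, _ = sd_features(plot)
    if sd_area == 0.0:
        raise DegeneratePlotError("zero ellipse area: CCM undefined")
    areas = triangle_areas(plot)
    return float(areas.sum() / (sd_area * areas.size))


def poincare_features(segment: Segment | np.ndarray, tau: int) -> PoincareFeatures:
    """All six descriptors of one segment at one lag."""
    plot = embed(segment, tau)
    sd1, sd2, sd_area, sd_ratio = sd_features(plot)
    r = correlation_r(plot)
    areas = triangle_areas(plot)
    return PoincareFeatures(
        sd1=sd1, sd2=sd2, sd_area=sd_area, sd_ratio=sd_ratio, r=r,
        ccm=float(areas.sum() / (sd_area * areas.size)), tau=int(tau),
    )


def feature_sweep(segments: list[Segment], tau_values) -> pd.DataFrame:
    """Long-format table of descriptors, one row per (segment, tau).

    Degenerate plots yield missing values (with a logged warning) rather
    than aborting the sweep.
    """
    rows = []
    for seg_id, seg in enumerate(segments):
        label = seg.label if isinstance(seg, Segment) else "unknown"
        for tau in tau_values:
            row = {"segment_id": seg_id, "label": label, "tau": int(tau)}
            try:
                f = poincare_features(seg, int(tau))
                row.update({"SD1": f.sd1, "SD2": f.sd2, "SDarea": f.sd_area,
                            "SDratio": f.sd_ratio, "R": f.r, "CCM": f.ccm})
            except DegeneratePlotError as exc:
                logger.warning("segment %d tau %d degenerate: %s", seg_id, tau, exc)
                row.update({k: np.nan for k in POINCARE_FEATURES})
            rows.append(row)
    columns = ["segment_id", "label", "tau", *POINCARE_FEATURES]
    return pd.DataFrame(rows, columns=columns)
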