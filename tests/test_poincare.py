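"""Poincaré descriptors: hand-computed values, identities, CCM oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regpoincare.errors import DegeneratePlotError, LagError
from regpoincare.poincare import (
    PoincarePlot, ccm, correlation_r, embed, feature_sweep, sd_descriptors,
    sd_features,
)

from conftest import sine_segment


def ccm_oracle(series, tau):
    """Brute-force CCM: shoelace triangle areas and textbook variances.

    Pure-Python reimplementation, independent of the vectorised code path.
    """
    x = [float(v) for v in series]
    n = len(x)
    pts = [(x[i], x[i + tau]) for i in range(n - tau)]

    def stdev(vals):
        m = sum(vals) / len(vals)
        return math.sqrt(sum((v - m) ** 2 for v in vals) / (len(vals) - 1))

    sd1 = stdev([(px - py) / math.sqrt(2) for px, py in pts])
    sd2 = stdev([(px + py) / math.sqrt(2) for px, py in pts])
    total = 0.0
    for i in range(len(pts) - 2):
        (x1, y1), (x2, y2), (x3, y3) = pts[i], pts[i + 1], pts[i + 2]
        total += 0.5 * abs(x1 * (y2 - y3) + x2 * (y3 - y1) + x3 * (y1 - y2))
    return total / (math.pi * sd1 * sd2 * (len(pts) - 2))


class TestEmbed:
    def test_point_count(self):
        plot = embed(np.arange(4000, dtype=float), 70)
        assert plot.n_points == 3930

    def test_pairs(self):
        plot = embed(np.array([1.0, 2.0, 3.0, 4.0]), 1)
        np.testing.assert_array_equal(plot.x, [1, 2, 3])
        np.testing.assert_array_equal(plot.y, [2, 3, 4])

    @pytest.mark.parametrize("tau", [0, 3, 8, -1])
    def test_out_of_range_lag(self, tau):
        with pytest.raises(LagError):
            embed(np.arange(5, dtype=float), tau)


class TestSdFeatures:
    def test_hand_computed_alternating_series(self):
        plot = embed(np.array([0.0, 1.0, 0.0, 1.0, 0.0]), 1)
        sd1, sd2, area = sd_descriptors(plot)
        assert sd1 == pytest.approx(math.sqrt(2.0 / 3.0), abs=1e-12)
        assert sd2 == pytest.approx(0.0, abs=1e-12)
        assert area == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(DegeneratePlotError):
            sd_features(plot)

    def test_constant_series_is_degenerate_with_zero_spread(self):
        plot = embed(np.full(50, 3.7), 2)
        sd1, sd2, area = sd_descriptors(plot)
        assert sd1 == sd2 == area == 0.0

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(0, 2**31 - 1), st.integers(8, 60), st.integers(1, 3))
    def test_rotation_identity(self, seed, n, tau):
        """sd1^2 + sd2^2 = var(x) + var(y): the 45-degree rotation preserves
        total variance."""
        x = np.random.default_rng(seed).normal(size=n)
        plot = embed(x, tau)
        sd1, sd2, _ = sd_descriptors(plot)
        total = np.var(plot.x, ddof=1) + np.var(plot.y, ddof=1)
        assert sd1**2 + sd2**2 == pytest.approx(total, rel=1e-10)

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(0, 2**31 - 1), st.integers(10, 60), st.integers(1, 3))
    def test_circular_identity_links_ratio_and_r(self, seed, n, tau):
        """On a circularly rolled series (equal-variance axes),
        sd_ratio^2 = (1 - r) / (1 + r)."""
        x = np.random.default_rng(seed).normal(size=n)
        plot = PoincarePlot(x=x, y=np.roll(x, -tau), tau=tau)
        _, _, _, ratio = sd_features(plot)
        r = correlation_r(plot)
        assert ratio**2 == pytest.approx((1 - r) / (1 + r), rel=1e-10)


class TestCorrelationR:
    def test_identity_plot(self):
        x = np.random.default_rng(3).normal(size=100)
        plot = PoincarePlot(x=x, y=x.copy(), tau=0)
        assert correlation_r(plot) == pytest.approx(1.0, abs=1e-12)

    def test_sine_quarter_period_decorrelates(self):
        seg = sine_segment(period_samples=248, n_cycles=12)
        assert abs(correlation_r(embed(seg, 62))) < 0.02

    def test_sine_half_period_antiphase(self):
        seg = sine_segment(period_samples=248, n_cycles=12)
        assert correlation_r(embed(seg, 124)) == pytest.approx(-1.0, abs=1e-3)

    def test_zero_variance_raises(self):
        plot = PoincarePlot(x=np.zeros(10), y=np.arange(10.0), tau=1)
        with pytest.raises(DegeneratePlotError):
            correlation_r(plot)


class TestCcm:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12345)
        checked = 0
        for _ in range(120):
            n = int(rng.integers(10, 51))
            tau = int(rng.integers(1, 4))
            if n - tau < 5:
                continue
            x = rng.normal(size=n)
            assert ccm(x, tau) == pytest.approx(ccm_oracle(x, tau), abs=1e-12)
            checked += 1
        assert checked >= 100

    def test_collinear_points_contribute_zero(self):
        from regpoincare.poincare import triangle_areas

        plot = PoincarePlot(x=np.array([0.0, 1.0, 2.0]),
                            y=np.array([0.0, 1.0, 2.0]), tau=1)
        assert triangle_areas(plot)[0] == 0.0

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 2**31 - 1),
           st.floats(-5, 5).filter(lambda c: abs(c) > 1e-3),
           st.floats(-10, 10))
    def test_affine_invariance(self, seed, scale, offset):
        x = np.random.default_rng(seed).normal(size=40)
        base = ccm(x, 2)
        assert ccm(scale * x + offset, 2) == pytest.approx(base, rel=1e-9)

    def test_degenerate_raises(self):
        with pytest.raises(DegeneratePlotError):
            ccm(np.zeros(30), 1)


class TestFeatureSweep:
    def test_study_sweep_row_count(self, default_sweep):
        assert len(default_sweep) == 3710  # 53 segments x lags 1..70
        assert default_sweep[["SD1", "SD2", "SDarea", "SDratio", "R", "CCM"]].notna().all().all()

    def test_single_row(self, default_dataset):
        table = feature_sweep(default_dataset[:1], [5])
        assert len(table) == 1
        assert np.isfinite(table.iloc[0][["SD1", "SD2", "SDarea", "SDratio",
                                          "R", "CCM"]].astype(float)).all()

    def test_empty_inputs(self):
        assert len(feature_sweep([], [1, 2])) == 0

    def test_monotone_trends_in_lag(self, default_sweep):
        """SD1 grows and SD2 shrinks as the lag unfolds the attractor."""
        from scipy.stats import spearmanr

        med = default_sweep.groupby("tau")[["SD1", "SD2"]].median()
        rho1, p1 = spearmanr(med.index, med["SD1"])
        rho2, p2 = spearmanr(med.index, med["SD2"])
        assert rho1 > 0.99 and p1 < 0.01
        assert rho2 < -0.99 and p2 < 0.01
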