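import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncis import (
    DegenerateDataError,
    FitFailureError,
    GrowthCurve,
    InsufficientDataError,
    InvalidGeometryError,
    InvalidInputError,
    SigmoidParams,
    TwoRegionGeometry,
    UnifiedGrowthParams,
    fit_sigmoid,
    fit_unified,
    sigmoid_value,
    two_region_re_dz,
    unified_growth,
    wall_radius,
)

pytestmark = pytest.mark.filterwarnings("ignore:stage-1 lags inverted")

# Printed fit parameters: bottle 50 kHz real channel and well-plate 160 MHz.
BOTTLE_SIGMOID = SigmoidParams(ua=4550.0, tau=0.25, t0=6.0)
WELLPLATE_SIGMOID = SigmoidParams(ua=-10.0, tau=1.0, t0=17.2)


class TestSigmoidValue:
    def test_midpoint_is_half_amplitude(self):
        assert sigmoid_value(BOTTLE_SIGMOID, 6.0) == pytest.approx(2275.0)

    def test_limits(self):
        assert sigmoid_value(BOTTLE_SIGMOID, -1e4) == pytest.approx(0.0, abs=1e-12)
        assert sigmoid_value(BOTTLE_SIGMOID, 1e4) == pytest.approx(4550.0)

    def test_strictly_monotone(self):
        t = np.linspace(0, 12, 400)
        vals = sigmoid_value(BOTTLE_SIGMOID, t)
        assert np.all(np.diff(vals) > 0)
        down = sigmoid_value(WELLPLATE_SIGMOID, np.linspace(12, 22, 200))
        assert np.all(np.diff(down) < 0)

    def test_parameter_invariants(self):
        with pytest.raises(InvalidInputError):
            SigmoidParams(ua=1.0, tau=-0.5, t0=6.0)
        with pytest.raises(InvalidInputError):
            SigmoidParams(ua=0.0, tau=0.5, t0=6.0)


class TestFitSigmoid:
    def test_noise_free_recovery_wellplate_channel(self):
        """Printed well-plate parameters recovered to 1e-6 relative."""
        t = np.linspace(12, 22, 120)
        curve = GrowthCurve(t, sigmoid_value(WELLPLATE_SIGMOID, t))
        p = fit_sigmoid(curve).params
        assert p.ua == pytest.approx(-10.0, rel=1e-6)
        assert p.tau == pytest.approx(1.0, rel=1e-6)
        assert p.t0 == pytest.approx(17.2, rel=1e-6)

    def test_monte_carlo_tau_recovery_at_1pct_noise(self):
        """Median tau estimate within 10% of truth over 50 seeds."""
        t = np.linspace(4.5, 7.5, 100)
        clean = sigmoid_value(BOTTLE_SIGMOID, t)
        taus = []
        for seed in range(1, 51):
            rng = np.random.default_rng(seed)
            noisy = clean * (1.0 + 0.01 * rng.standard_normal(t.size))
            taus.append(fit_sigmoid(GrowthCurve(t, noisy)).params.tau)
        assert np.median(taus) == pytest.approx(0.25, rel=0.10)

    def test_constant_curve_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fit_sigmoid(GrowthCurve(np.arange(5.0), np.full(5, 3.3)))

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_sigmoid(GrowthCurve([0.0, 1.0, 2.0], [0.0, 0.5, 1.0]))


class TestWallRadius:
    def test_before_lag_full_radius(self):
        assert wall_radius(3.0, t0w=5.6, tau_u=1.0, r2=0.04) == 0.04

    def test_one_efold_at_three_tau(self):
        val = wall_radius(5.6 + 3.0, t0w=5.6, tau_u=1.0, r2=0.04)
        assert val == pytest.approx(0.04 / np.e, rel=1e-12)

    def test_continuous_and_non_increasing(self):
        t = np.linspace(0, 20, 2000)
        r = wall_radius(t, t0w=5.6, tau_u=1.0, r2=0.04)
        assert np.all(np.diff(r) <= 0)
        # continuity across the lag
        eps = 1e-9
        assert wall_radius(5.6 + eps, 5.6, 1.0, 0.04) == \
            pytest.approx(wall_radius(5.6 - eps, 5.6, 1.0, 0.04), rel=1e-6)


class TestTwoRegion:
    GEOM = TwoRegionGeometry(r2=0.04, h=0.06, rho_a1=2.0, rho_a2=1.0)

    def test_homogeneous_medium_independent_of_r1(self):
        rho = 1.7
        expected = self.GEOM.h * rho / (np.pi * self.GEOM.r2**2)
        for r1 in (0.01, 0.02, 0.04):
            assert two_region_re_dz(self.GEOM, rho, rho, r1) == \
                pytest.approx(expected, rel=1e-12)

    def test_no_wall_region(self):
        val = two_region_re_dz(self.GEOM, 2.0, 5.0, self.GEOM.r2)
        assert val == pytest.approx(self.GEOM.h * 2.0 / (np.pi * self.GEOM.r2**2),
                                    rel=1e-12)

    def test_parallel_conductance_oracle(self, rng):
        """Equals 1/(G1+G2) with the two cylinder conductances computed
        independently."""
        for _ in range(100):
            r2 = rng.uniform(0.01, 0.1)
            geom = TwoRegionGeometry(r2=r2, h=rng.uniform(0.01, 0.2),
                                     rho_a1=rng.uniform(0.1, 10),
                                     rho_a2=rng.uniform(0.1, 10))
            r1 = rng.uniform(0.1, 1.0) * r2
            rho1, rho2 = rng.uniform(0.1, 10, 2)
            g1 = np.pi * r1**2 / (rho1 * geom.h)
            g2 = np.pi * (r2**2 - r1**2) / (rho2 * geom.h)
            assert two_region_re_dz(geom, rho1, rho2, r1) == \
                pytest.approx(1.0 / (g1 + g2), rel=1e-12)

    def test_invalid_geometry(self):
        with pytest.raises(InvalidGeometryError):
            two_region_re_dz(self.GEOM, 1.0, 1.0, self.GEOM.r2 * 1.5)


S_EPI = UnifiedGrowthParams(un=1.0, tau_u=1.0, t0w=5.6, t0b=7.2, rho_ratio=3.5)


class TestUnifiedGrowth:
    def test_late_time_asymptote(self):
        assert unified_growth(S_EPI, 1e4) == pytest.approx(1.0 * 3.5, rel=1e-12)

    def test_branch_continuity_at_wall_lag(self):
        """Both branch expressions agree at t = t0w."""
        p = S_EPI
        sig = 1.0 / (1.0 + np.exp(-(p.t0w - p.t0b) / p.tau_u))
        upper = p.un * (1.0 * sig + 0.0 * p.rho_ratio)  # decay term = 1 at t0w
        lower = p.un * sig
        assert upper == pytest.approx(lower, abs=1e-12)
        assert unified_growth(p, p.t0w) == pytest.approx(lower, rel=1e-12)

    def test_reduces_to_sigmoid_before_wall_lag(self):
        t = np.linspace(0, S_EPI.t0w - 1e-9, 50)
        sig = SigmoidParams(ua=S_EPI.un, tau=S_EPI.tau_u, t0=S_EPI.t0b)
        assert np.allclose(unified_growth(S_EPI, t), sigmoid_value(sig, t),
                           rtol=0, atol=1e-15)

    def test_asymptote_reached_within_1pct_by_ten_tau(self, rng):
        for _ in range(30):
            p = UnifiedGrowthParams(
                un=rng.uniform(0.5, 2.0), tau_u=rng.uniform(0.2, 2.0),
                t0w=rng.uniform(2, 6), t0b=rng.uniform(2, 8),
                rho_ratio=rng.uniform(0.1, 5.0))
            val = unified_growth(p, p.t0w + 10 * p.tau_u)
            assert val == pytest.approx(p.un * p.rho_ratio, rel=0.01)

    def test_wall_dominant_curve_rises_earlier(self):
        """rho_ratio = 3.5 is non-decreasing, dominates the rho_ratio = 0.7
        curve pointwise and crosses any absolute threshold no later."""
        t = np.linspace(0, 20, 4000)
        hi = np.asarray(unified_growth(S_EPI, t))
        lo_p = UnifiedGrowthParams(un=1.0, tau_u=1.0, t0w=5.6, t0b=7.2,
                                   rho_ratio=0.7)
        lo = np.asarray(unified_growth(lo_p, t))
        assert np.all(np.diff(hi) >= -1e-12)
        assert np.all(hi >= lo)
        for threshold in (0.1, 0.35, 0.6):
            assert t[np.argmax(hi >= threshold)] <= t[np.argmax(lo >= threshold)]


def _unified_pair_curves(t, t0w, t0b, rho_lo, rho_hi, noise_sd=0.0, seed=None):
    lo_p = UnifiedGrowthParams(un=1.0, tau_u=1.0, t0w=t0w, t0b=t0b,
                               rho_ratio=rho_lo)
    hi_p = UnifiedGrowthParams(un=1.0, tau_u=1.0, t0w=t0w, t0b=t0b,
                               rho_ratio=rho_hi)
    y_lo = np.asarray(unified_growth(lo_p, t))
    y_hi = np.asarray(unified_growth(hi_p, t))
    if noise_sd:
        rng = np.random.default_rng(seed)
        y_lo = y_lo * (1 + noise_sd * rng.standard_normal(t.size))
        y_hi = y_hi * (1 + noise_sd * rng.standard_normal(t.size))
    return GrowthCurve(t, y_lo), GrowthCurve(t, y_hi)


class TestFitUnified:
    @pytest.mark.parametrize("t0w,t0b,rho_lo,rho_hi",
                             [(5.6, 7.2, 3.5, 0.7), (3.7, 5.4, 3.5, 0.5)])
    def test_noise_free_recovery(self, t0w, t0b, rho_lo, rho_hi):
        t = np.linspace(0, 14, 200)
        low, high = _unified_pair_curves(t, t0w, t0b, rho_lo, rho_hi)
        fit = fit_unified(low, high)
        tau_u, t0w_hat, t0b_hat = fit.shared
        assert tau_u == pytest.approx(1.0, rel=1e-3)
        assert t0w_hat == pytest.approx(t0w, rel=1e-3)
        assert t0b_hat == pytest.approx(t0b, rel=1e-3)
        assert fit.params_low.rho_ratio == pytest.approx(rho_lo, rel=1e-3)
        assert fit.params_high.rho_ratio == pytest.approx(rho_hi, rel=1e-3)

    def test_monte_carlo_recovery_at_1pct_noise(self):
        """Median lags within 0.2 h and rho ratio within 15% over 50 seeds."""
        t = np.linspace(0, 14, 200)
        t0ws, t0bs, rhos = [], [], []
        for seed in range(1, 51):
            low, high = _unified_pair_curves(t, 3.7, 5.4, 3.5, 0.5,
                                             noise_sd=0.01, seed=seed)
            fit = fit_unified(low, high)
            _, t0w_hat, t0b_hat = fit.shared
            t0ws.append(t0w_hat)
            t0bs.append(t0b_hat)
            rhos.append(fit.params_low.rho_ratio)
        assert abs(np.median(t0ws) - 3.7) < 0.2
        assert abs(np.median(t0bs) - 5.4) < 0.2
        assert np.median(rhos) == pytest.approx(3.5, rel=0.15)

    def test_frozen_lag_procedure_uses_stage1_lags(self):
        """refine=False keeps the individual-fit lags verbatim."""
        t = np.linspace(0, 14, 200)
        low, high = _unified_pair_curves(t, 5.6, 7.2, 3.5, 0.7)
        fit = fit_unified(low, high, refine=False)
        assert not fit.refined
        assert fit.shared[1] == fit.stage1_low.params.t0
        assert fit.shared[2] == fit.stage1_high.params.t0
        assert fit.shared[0] == pytest.approx(abs(fit.stage1_high.params.tau))

    def test_swapped_pair_warns_without_reordering(self):
        """Sigmoid-shaped channels passed in the wrong order raise the
        lag-order flag; channels are not silently reordered."""
        t = np.linspace(0, 14, 200)
        early = GrowthCurve(t, sigmoid_value(SigmoidParams(1.0, 0.5, 3.7), t))
        late = GrowthCurve(t, sigmoid_value(SigmoidParams(1.0, 1.0, 5.4), t))
        with pytest.warns(UserWarning, match="lag"):
            fit = fit_unified(late, early)  # swapped on purpose
        assert "lag_order" in fit.warnings
        ok = fit_unified(early, late)
        assert "lag_order" not in ok.warnings

    def test_stage1_failure_propagates(self):
        t = np.arange(6.0)
        flat = GrowthCurve(t, np.ones_like(t))
        rising = GrowthCurve(t, np.linspace(0, 1, 6))
        with pytest.raises(FitFailureError, match="stage-1"):
            fit_unified(flat, rising)


@settings(max_examples=40, deadline=None)
@given(
    tau_u=st.floats(0.2, 3.0),
    t0w=st.floats(1.0, 8.0),
    dt0=st.floats(0.1, 4.0),
    rho=st.floats(0.1, 8.0),
)
def test_unified_continuity_property(tau_u, t0w, dt0, rho):
    """The two branches of the growth signal meet at the wall lag for any
    admissible parameter draw."""
    p = UnifiedGrowthParams(un=1.0, tau_u=tau_u, t0w=t0w, t0b=t0w + dt0,
                            rho_ratio=rho)
    eps = 1e-12
    below = unified_growth(p, t0w - eps)
    at = unified_growth(p, t0w)
    above = unified_growth(p, t0w + eps)
    # slope near t0w is bounded by ~un*max(1/(4 tau), 2 rho/(3 tau))
    tol = 1e-12 * max(1.0, rho) * (3.0 / tau_u)
    assert at == pytest.approx(below, abs=tol)
    assert at == pytest.approx(above, abs=tol)
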