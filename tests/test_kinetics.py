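"""Rate estimation, unit conversion, detection limits, live/killed
comparison, Michaelis–Menten fitting (vs a grid-search oracle), and Q10
scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sedenz.calibration import StandardCurve
from sedenz.kinetics import (AssayGeometry, compare_live_killed, compute_v0,
                             convert_rate_units, detection_limit,
                             final_substrate_concentration,
                             fit_michaelis_menten, km_depth_trend,
                             michaelis_menten, temperature_adjust)

CURVE = StandardCurve("AMC", 1000.0, 50.0, 0.0, 0.0, 1.0, 6)


class TestDilution:
    @pytest.mark.parametrize("stock,aliquot,total,expected", [
        (20.0, 20.0, 1000.0, 400.0),   # the single-concentration design
        (20.0, 0.0, 1000.0, 0.0),
        (20.0, 36.0, 1000.0, 720.0),   # top level of the 0-720 layout
        (20.0, 40.0, 1000.0, 800.0),   # top level of the 0-800 layout
    ])
    def test_final_concentration(self, stock, aliquot, total, expected):
        assert final_substrate_concentration(stock, aliquot, total) == \
            pytest.approx(expected)

    def test_aliquot_exceeding_total_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            final_substrate_concentration(20, 1100, 1000)


class TestV0:
    def test_constant_series_gives_zero(self):
        est = compute_v0([0, 6, 12, 24], [3.0, 3.0, 3.0, 3.0])
        assert est.v0 == pytest.approx(0.0)

    def test_exact_linear_series(self):
        t = np.array([0, 6, 12, 24.0])
        est = compute_v0(t, 2.5 * t)
        assert est.v0 == pytest.approx(2.5)
        assert est.r_squared == pytest.approx(1.0)
        assert est.n == 4

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        t = np.array([0, 6, 12, 18, 24.0])
        c = 1.3 * t + rng.normal(0, 0.5, t.size)
        est = compute_v0(t, c)
        tbar = t.mean()
        slope = np.sum((t - tbar) * (c - c.mean())) / np.sum((t - tbar) ** 2)
        assert est.v0 == pytest.approx(slope, rel=1e-12)

    @pytest.mark.parametrize("t,c", [
        ([0, 6], [0, 1]),
        ([0, 6, 6, 24], [0, 1, 2, 3]),
    ])
    def test_bad_series_rejected(self, t, c):
        with pytest.raises(ValueError):
            compute_v0(t, c)

    def test_initial_linear_window_recovers_early_slope(self):
        """With late-time curvature from substrate depletion, the prefix
        window gets closer to the true initial rate than all-points OLS."""
        t = np.linspace(0, 24, 5)
        s0, v = 400.0, 30.0
        p = s0 * (1 - np.exp(-(v / s0) * t))
        full = compute_v0(t, p, window="all")
        init = compute_v0(t, p, window="initial-linear")
        assert abs(init.v0 - v) < abs(full.v0 - v)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(scale=st.floats(0.1, 100), shift=st.floats(-50, 50))
    def test_equivariance(self, scale, shift):
        t = np.array([0, 6, 12, 24.0])
        c = np.array([0.1, 1.4, 2.2, 5.0])
        base = compute_v0(t, c).v0
        assert compute_v0(t, scale * c).v0 == pytest.approx(scale * base, rel=1e-9)
        assert compute_v0(t, c + shift).v0 == pytest.approx(base, rel=1e-9)


class TestUnits:
    def test_default_geometry(self):
        assert convert_rate_units(0.3, AssayGeometry()) == pytest.approx(10.0)
        assert convert_rate_units(0.0, AssayGeometry()) == 0.0

    def test_hand_computation_alt_geometry(self):
        geom = AssayGeometry(sediment_mass_g=6, slurry_volume_ml=100,
                             reaction_volume_ml=2)
        v = 0.7134
        # 2 ml reaction holds 0.12 g sediment; v uM/h -> v*2 nmol/h / 0.12 g
        assert convert_rate_units(v, geom) == pytest.approx(v * 2 / 0.12)

    def test_conversion_is_linear_and_invertible(self):
        geom = AssayGeometry()
        from sedenz.kinetics import rate_per_g_to_uM
        for v in (0.0, 0.3, 7.7):
            assert rate_per_g_to_uM(convert_rate_units(v, geom), geom) == \
                pytest.approx(v)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            AssayGeometry(sediment_mass_g=0)


class TestDetectionLimit:
    def test_identical_blanks_give_zero(self):
        assert detection_limit([1.0, 1.0, 1.0]) == pytest.approx(0.0)

    def test_noise_mode_hand_arithmetic(self):
        # 3*20/(1000*24) uM/h, x100/3 per-gram: 0.0833 nmol/g/h
        dl = detection_limit(sigma_f=20.0, curve=CURVE, horizon_h=24.0, k=3.0)
        assert dl == pytest.approx(3 * 20 / (1000 * 24) * 100 / 3, rel=1e-12)
        assert dl == pytest.approx(0.08333, rel=1e-3)

    def test_override_passthrough(self):
        assert detection_limit(override=4.77e-2) == 4.77e-2

    def test_too_few_blanks_rejected(self):
        with pytest.raises(ValueError):
            detection_limit([1.0, 2.0])


class TestLiveKilled:
    def test_identical_triplicates_not_significant(self):
        res = compare_live_killed([5, 5.1, 4.9], [5, 5.1, 4.9])
        assert not res.significant

    def test_welch_hand_oracle(self):
        live, killed = [10.0, 11.0, 12.0], [1.0, 1.2, 0.8]
        res = compare_live_killed(live, killed)
        # Welch statistic assembled by hand
        l, k = np.array(live), np.array(killed)
        se = np.sqrt(l.var(ddof=1) / 3 + k.var(ddof=1) / 3)
        t = (l.mean() - k.mean()) / se
        df = se**4 / ((l.var(ddof=1) / 3) ** 2 / 2 + (k.var(ddof=1) / 3) ** 2 / 2)
        assert res.t == pytest.approx(t, rel=1e-12)
        assert res.p == pytest.approx(stats.t.sf(t, df), rel=1e-9)
        assert res.significant

    def test_all_zero_degenerate(self):
        res = compare_live_killed([0, 0, 0], [0, 0, 0])
        assert res.p == 1.0 and not res.significant and res.difference == 0.0


def _grid_search_mm(s, v, vmax_range, km_range, n=201, refinements=3):
    """Dense (V_max, K_m) grid search minimizing SSE, iteratively refined."""
    lo_v, hi_v = vmax_range
    lo_k, hi_k = km_range
    best = None
    for _ in range(refinements):
        vg = np.linspace(lo_v, hi_v, n)
        kg = np.linspace(lo_k, hi_k, n)
        pred = vg[:, None, None] * s[None, None, :] / (kg[None, :, None] + s)
        sse = ((pred - v[None, None, :]) ** 2).sum(axis=2)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        best = (vg[i], kg[j])
        dv, dk = (hi_v - lo_v) / (n - 1), (hi_k - lo_k) / (n - 1)
        lo_v, hi_v = vg[i] - 2 * dv, vg[i] + 2 * dv
        lo_k, hi_k = max(kg[j] - 2 * dk, 1e-6), kg[j] + 2 * dk
    return best


class TestMichaelisMenten:
    S = np.linspace(0, 800, 11)

    def test_noiseless_recovery(self):
        v = michaelis_menten(self.S, 10.0, 200.0)
        fit = fit_michaelis_menten(pd.DataFrame({"substrate_conc_uM": self.S,
                                                 "v": v}))
        assert fit.converged
        assert fit.vmax == pytest.approx(10.0, rel=1e-6)
        assert fit.km == pytest.approx(200.0, rel=1e-6)

    def test_noisy_fit_matches_grid_search_oracle(self):
        rng = np.random.default_rng(13)
        v = michaelis_menten(self.S, 10.0, 200.0) + rng.normal(0, 0.5, self.S.size)
        fit = fit_michaelis_menten(pd.DataFrame({"substrate_conc_uM": self.S,
                                                 "v": v}))
        assert fit.converged
        assert abs(fit.vmax - 10.0) < 3 * fit.vmax_se
        assert abs(fit.km - 200.0) < 3 * fit.km_se
        gv, gk = _grid_search_mm(self.S, v, (5.0, 20.0), (50.0, 500.0))
        assert fit.vmax == pytest.approx(gv, rel=1e-3)
        assert fit.km == pytest.approx(gk, rel=1e-3)

    def test_half_saturation_invariant(self):
        v = michaelis_menten(self.S, 8.0, 150.0)
        fit = fit_michaelis_menten(pd.DataFrame({"substrate_conc_uM": self.S,
                                                 "v": v}))
        assert fit.predict(fit.km) == pytest.approx(fit.vmax / 2, rel=1e-9)
        assert np.all(fit.predict(self.S[1:]) < fit.vmax)

    def test_no_signal_flagged_not_raised(self):
        fit = fit_michaelis_menten(pd.DataFrame({
            "substrate_conc_uM": self.S, "v": np.zeros(11) - 0.01}))
        assert not fit.converged
        assert "no signal" in fit.message

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_michaelis_menten(pd.DataFrame({
                "substrate_conc_uM": [0, 100, 200, 400],
                "v": [0, 1, 2, 3]}))

    def test_single_conc_underestimates_vmax_by_saturation_factor(self):
        """The 400 uM single-concentration design reads V_max * S/(Km+S)."""
        vmax, km, s = 10.0, 200.0, 400.0
        assert michaelis_menten(s, vmax, km) == \
            pytest.approx(vmax * s / (km + s), rel=1e-12)


class TestKmDepthTrend:
    def test_exact_linear_trend(self):
        depths = np.array([5.0, 10, 20, 30, 40])
        fits = pd.DataFrame({"depth_mbsf": depths, "km": 100 + 5 * depths})
        slope, p, n = km_depth_trend(fits)
        assert slope == pytest.approx(5.0)
        assert n == 5

    def test_too_few_depths_rejected(self):
        with pytest.raises(ValueError):
            km_depth_trend(pd.DataFrame({"depth_mbsf": [1, 2], "km": [1, 2]}))


class TestTemperature:
    def test_q10_scaling(self):
        assert temperature_adjust(5.0, 2.0, 0.0) == 5.0
        assert temperature_adjust(5.0, 2.0, 10.0) == pytest.approx(10.0)
        # a 12 C offset at Q10=2 is a factor 2^1.2 = 2.2974
        assert temperature_adjust(1.0, 2.0, 12.0) == pytest.approx(2.2974, rel=1e-4)

    def test_invalid_q10_rejected(self):
        with pytest.raises(ValueError):
            temperature_adjust(1.0, 0.0, 5.0)
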