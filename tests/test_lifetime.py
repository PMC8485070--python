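"""Enzyme-lifetime bound: unit-safe closed forms, Monte-Carlo convergence,
and scenario algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sedenz.dists import log_uniform, point
from sedenz.lifetime import (LifetimeInputs, closed_form_lifetime_days,
                             enzyme_concentration, lifetime_bound,
                             monte_carlo_lifetime, respiration_per_gram,
                             sensitivity_table)


class TestClosedForms:
    def test_enzyme_concentration(self):
        assert enzyme_concentration(0.0, 1e3) == 0.0
        assert enzyme_concentration(1e-9, 1e3) == pytest.approx(1e-12)
        assert enzyme_concentration(1e-9, 1e3, sorption_factor=3.0) == \
            pytest.approx(3e-12)

    def test_lifetime_identity(self):
        assert lifetime_bound(1.0, 1.0, 1.0) == pytest.approx(1.0)

    def test_hand_unit_conversion_case(self):
        """E=1e-12 mol C/g, GE=0.1, Rc=0.1 nmol C/cm3/day at density 1:
        Rc per gram is 4.1667e-12 mol C/g/h, so tau = 2.4 h."""
        rc = respiration_per_gram(0.1, 1.0)
        assert rc == pytest.approx(0.1e-9 / 24, rel=1e-12)
        assert lifetime_bound(1e-12, 0.1, rc) == pytest.approx(2.4, rel=1e-12)

    def test_doubling_ge_halves_tau(self):
        rc = respiration_per_gram(0.1)
        assert lifetime_bound(1e-12, 0.2, rc) == \
            pytest.approx(lifetime_bound(1e-12, 0.1, rc) / 2)

    def test_unit_invariance(self):
        """Expressing Rc volumetrically at density 2 or halving it per gram
        gives the identical tau."""
        a = lifetime_bound(1e-12, 0.1, respiration_per_gram(0.1, 2.0))
        b = lifetime_bound(1e-12, 0.1, respiration_per_gram(0.05, 1.0))
        assert a == pytest.approx(b, rel=1e-12)

    @pytest.mark.parametrize("bad", [
        lambda: enzyme_concentration(1e-9, 0.0),
        lambda: lifetime_bound(1e-12, 0.0, 1e-12),
        lambda: lifetime_bound(1e-12, 0.1, 0.0),
        lambda: respiration_per_gram(0.1, 0.0),
    ])
    def test_nonpositive_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            bad()

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(c=st.floats(0.1, 10))
    def test_homogeneity(self, c):
        """tau is degree 1 in V_max and degree -1 in SA, GE, Rc."""
        base = lifetime_bound(enzyme_concentration(1e-9, 1e3), 0.1, 4e-12)
        assert lifetime_bound(enzyme_concentration(c * 1e-9, 1e3), 0.1, 4e-12) \
            == pytest.approx(c * base, rel=1e-9)
        assert lifetime_bound(enzyme_concentration(1e-9, c * 1e3), 0.1, 4e-12) \
            == pytest.approx(base / c, rel=1e-9)
        assert lifetime_bound(enzyme_concentration(1e-9, 1e3), c * 0.1, 4e-12) \
            == pytest.approx(base / c, rel=1e-9)
        assert lifetime_bound(enzyme_concentration(1e-9, 1e3), 0.1, c * 4e-12) \
            == pytest.approx(base / c, rel=1e-9)


class TestMonteCarlo:
    def test_point_masses_equal_closed_form(self):
        inputs = LifetimeInputs(vmax_nmol_g_h=1.0, sa_dist=point(1e3),
                                n_draws=1000, seed=5)
        est = monte_carlo_lifetime(inputs)
        cf = closed_form_lifetime_days(inputs)
        assert est.median_days == pytest.approx(cf, rel=1e-12)
        assert est.iqr_days[0] == pytest.approx(cf, rel=1e-12)
        assert est.p95_days == pytest.approx(cf, rel=1e-12)

    def test_loguniform_median_is_geometric_mean_closed_form(self):
        inputs = LifetimeInputs(vmax_nmol_g_h=1.0,
                                sa_dist=log_uniform(1e2, 1e4),
                                n_draws=100_000, seed=5)
        est = monte_carlo_lifetime(inputs)
        assert est.median_days == pytest.approx(
            closed_form_lifetime_days(inputs), rel=0.02)

    def test_mc_error_shrinks_with_draws(self):
        cf = None
        errs = []
        for n in (2_000, 128_000):
            inputs = LifetimeInputs(vmax_nmol_g_h=1.0,
                                    sa_dist=log_uniform(1e2, 1e4),
                                    n_draws=n, seed=11)
            cf = closed_form_lifetime_days(inputs)
            errs.append(abs(monte_carlo_lifetime(inputs).median_days - cf))
        # 64x the draws should cut the median's MC error roughly 8-fold
        assert errs[1] < errs[0] / 2

    def test_percentiles_ordered_and_positive(self):
        est = monte_carlo_lifetime(LifetimeInputs(
            vmax_nmol_g_h=1.0, sa_dist=log_uniform(10, 1e5), n_draws=5000,
            seed=2))
        assert 0 < est.p5_days <= est.iqr_days[0] <= est.median_days \
            <= est.iqr_days[1] <= est.p95_days


class TestScenarios:
    BASE = dict(vmax_nmol_g_h=1.0, sa_dist=point(1e3), n_draws=2000, seed=3)

    def test_baseline_row_equals_single_run(self):
        inputs = LifetimeInputs(**self.BASE)
        tab = sensitivity_table(inputs, [{"label": "baseline"}])
        assert len(tab) == 1
        assert tab["median_days"].iloc[0] == pytest.approx(
            monte_carlo_lifetime(inputs).median_days)

    def test_ge_grid_scales_inverse(self):
        inputs = LifetimeInputs(**self.BASE)
        tab = sensitivity_table(inputs, [
            {"label": "low GE", "growth_efficiency": 0.037},
            {"label": "base GE", "growth_efficiency": 0.10},
        ]).set_index("scenario")
        ratio = tab.loc["low GE", "median_days"] / tab.loc["base GE", "median_days"]
        assert ratio == pytest.approx(0.10 / 0.037, rel=1e-12)

    def test_sorption_and_low_ge_factor(self):
        """f_s=3 with GE=3.7% lengthens the bound by 3*(0.10/0.037) = 8.108
        relative to f_s=1, GE=10% — the 'order of magnitude' scenario."""
        inputs = LifetimeInputs(**self.BASE)
        tab = sensitivity_table(inputs, [
            {"label": "baseline"},
            {"label": "combined", "sorption_factor": 3.0,
             "growth_efficiency": 0.037},
        ]).set_index("scenario")
        ratio = tab.loc["combined", "median_days"] / tab.loc["baseline", "median_days"]
        assert ratio == pytest.approx(3 * 0.10 / 0.037, rel=1e-12)

    def test_rerun_reproduces_table(self):
        inputs = LifetimeInputs(vmax_nmol_g_h=1.0,
                                sa_dist=log_uniform(1e2, 1e4),
                                n_draws=3000, seed=7)
        scenarios = [{"label": "a"}, {"label": "b", "sorption_factor": 2.0},
                     {"label": "c", "growth_efficiency": 0.05}]
        t1 = sensitivity_table(inputs, scenarios)
        t2 = sensitivity_table(inputs, scenarios)
        assert t1.to_csv() == t2.to_csv()

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            sensitivity_table(LifetimeInputs(**self.BASE),
                              [{"label": "x"}, {"label": "x"}])

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            LifetimeInputs(vmax_nmol_g_h=1.0, sa_dist=point(1e3),
                           growth_efficiency=1.5)
        with pytest.raises(ValueError):
            LifetimeInputs(vmax_nmol_g_h=1.0, sa_dist=point(1e3),
                           sorption_factor=0.5)
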