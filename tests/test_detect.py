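import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cohortbump as cb
from cohortbump.basis import BasisSpec, CohortBump


class TestClassifyLocal:
    def test_wide_bump_is_not_local(self):
        """A width of 21 years on a >100-year birth span is a global
        trend, not a local cohort effect."""
        is_local, ratio = cb.classify_local(CohortBump(1920.0, 21.0), 130.0)
        assert not is_local
        assert ratio == pytest.approx(21.0 / 130.0)

    @pytest.mark.parametrize("sigma", [3.0, 4.0])
    def test_narrow_bump_is_local(self, sigma):
        is_local, _ = cb.classify_local(CohortBump(1934.0, sigma), 130.0)
        assert is_local

    def test_boundary_counts_as_local(self):
        is_local, ratio = cb.classify_local(CohortBump(1950.0, 5.0), 100.0)
        assert ratio == pytest.approx(0.05)
        assert is_local

    def test_tiny_sigma_always_local(self):
        assert cb.classify_local(CohortBump(1950.0, 1e-9), 1.0)[0]

    def test_nonpositive_span_rejected(self):
        with pytest.raises(ValueError):
            cb.classify_local(CohortBump(1950.0, 4.0), 0.0)


class TestPeakRelativeRisk:
    @pytest.mark.parametrize("beta_c,sigma,expected", [
        (4.3470, 4.0, 1.54),   # elevated liver-cancer-like cohort
        (-1.3787, 3.0, 0.83),  # protected lung-cancer-like cohort
        (-4.24, 7.0, 0.79),    # rectum-like negative effect
    ])
    def test_closed_form_extremes(self, beta_c, sigma, expected):
        assert round(cb.peak_relative_risk(beta_c, sigma), 2) == expected

    @settings(deadline=None, max_examples=30)
    @given(sigma=st.floats(0.1, 50))
    def test_null_coefficient_gives_unit_risk(self, sigma):
        assert cb.peak_relative_risk(0.0, sigma) == 1.0

    def test_requires_positive_sigma(self):
        with pytest.raises(ValueError):
            cb.peak_relative_risk(1.0, -1.0)


@pytest.fixture(scope="module")
def bump_fit(sim_positive):
    spec = BasisSpec.from_table(sim_positive)
    return cb.fit_ml(sim_positive, spec, CohortBump(1950.0, 4.0))


class TestRelativeRiskCurve:
    def test_symmetric_about_mu_c(self, bump_fit):
        delta = np.linspace(0.0, 30.0, 61)
        up = cb.relative_risk_curve(bump_fit, 1950.0 + delta)
        dn = cb.relative_risk_curve(bump_fit, 1950.0 - delta)
        np.testing.assert_allclose(up["relative_risk"], dn["relative_risk"],
                                   rtol=1e-12)

    def test_tends_to_one_in_the_tails(self, bump_fit):
        far = cb.relative_risk_curve(bump_fit, [1950.0 - 40, 1950.0 + 40])
        np.testing.assert_allclose(far["relative_risk"], 1.0, atol=1e-12)

    def test_peak_matches_closed_form(self, bump_fit):
        at_mu = cb.relative_risk_curve(bump_fit, [1950.0])
        assert at_mu["relative_risk"][0] == pytest.approx(
            cb.peak_relative_risk(bump_fit.beta_c, 4.0), rel=1e-12)

    def test_monotone_toward_the_center(self, bump_fit):
        c = np.arange(1920.0, 1950.5)
        rr = cb.relative_risk_curve(bump_fit, c)["relative_risk"].to_numpy()
        sign = np.sign(bump_fit.beta_c)
        assert np.all(sign * np.diff(rr) >= 0)

    def test_requires_a_bump(self, sim_positive):
        f = cb.fit_ml(sim_positive)
        with pytest.raises(ValueError):
            cb.relative_risk_curve(f, [1950.0])


class TestGridSearch:
    def test_single_grid_point_is_best(self, sim_positive):
        gs = cb.grid_search(sim_positive, mu_grid=[1950.0],
                            sigma_grid=[4.0])
        assert gs.best == CohortBump(1950.0, 4.0)
        assert len(gs.grid) == 1

    def test_best_deviance_at_most_null(self, sim_positive, sim_null):
        for t in (sim_positive, sim_null):
            gs = cb.grid_search(t, mu_grid=np.arange(1940.0, 1961.0, 5),
                                sigma_grid=[2.0, 4.0, 8.0])
            assert gs.best_fit.deviance_stat <= gs.null_fit.deviance_stat
            ok = gs.grid["deviance"].dropna()
            assert (gs.best_fit.deviance_stat <= ok + 1e-9).all()

    def test_mu_grid_must_lie_in_birth_range(self, sim_positive):
        with pytest.raises(ValueError, match="birth-year range"):
            cb.grid_search(sim_positive, mu_grid=[1850.0],
                           sigma_grid=[4.0])

    def test_recovers_planted_bump_center(self):
        """Seeded single-replicate recovery of the planted (1950, 4)."""
        t = cb.simulate_table(cb.default_scenario("bump-positive", seed=3))
        gs = cb.grid_search(t, mu_grid=np.arange(1940.0, 1961.0),
                            sigma_grid=np.arange(1.0, 9.0))
        assert abs(gs.best.mu_c - 1950.0) <= 1.0
        assert abs(gs.best.sigma_c - 4.0) <= 1.0

    def test_null_deviance_drop_is_modest(self):
        """Under beta_c = 0 the best-over-grid deviance improvement
        behaves like the extreme of correlated chi-square deviates; its
        median over replicates stays in single digits (calibrated by
        simulation)."""
        drops = []
        for seed in range(40):
            t = cb.simulate_table(cb.default_scenario("null",
                                                      seed=2000 + seed))
            gs = cb.grid_search(t, mu_grid=np.arange(1930.0, 1971.0, 2),
                                sigma_grid=np.arange(1.0, 11.0, 2))
            drops.append(gs.null_fit.deviance_stat
                         - gs.best_fit.deviance_stat)
        assert np.median(drops) < 12.0


class TestDetectPipeline:
    def test_positive_scenario_detected_as_local(self, sim_positive):
        res = cb.detect(sim_positive, mu_grid=np.arange(1935.0, 1966.0),
                        sigma_grid=np.arange(1.0, 9.0))
        assert abs(res.bump.mu_c - 1950.0) <= 2.0
        assert res.beta_c.estimate > 0
        assert res.beta_c.p_value < 0.001
        assert res.is_local
        assert res.rr_extreme > 1.0

    def test_negative_scenario_gives_protective_rr(self):
        t = cb.simulate_table(cb.default_scenario("bump-negative", seed=5))
        res = cb.detect(t, mu_grid=np.arange(1940.0, 1961.0),
                        sigma_grid=np.arange(1.0, 9.0))
        assert res.beta_c.estimate < 0
        assert res.rr_extreme < 1.0

    def test_rr_extreme_consistent_with_curve(self, sim_positive):
        res = cb.detect(sim_positive, mu_grid=[1950.0], sigma_grid=[4.0])
        assert res.rr_extreme == pytest.approx(
            cb.peak_relative_risk(res.beta_c.estimate, 4.0))
        assert res.rr_curve["relative_risk"].max() <= res.rr_extreme + 1e-12


class TestPredictSurface:
    def test_intercept_only_surface_is_constant(self, small_table):
        f = cb.fit_ml(small_table, BasisSpec.from_table(small_table, 0, 0))
        surf = cb.predict_surface(f, [40.0, 50.0], [1960.0, 1980.0])
        np.testing.assert_allclose(surf["rates"],
                                   np.exp(f.theta[0]) * np.ones((2, 2)))
        assert not surf["extrapolated"]

    def test_surface_is_finite_positive_on_data_grid(self, sim_positive):
        spec = BasisSpec.from_table(sim_positive)
        f = cb.fit_ml(sim_positive, spec, CohortBump(1950.0, 4.0))
        surf = cb.predict_surface(f, np.unique(sim_positive.ages),
                                  np.unique(sim_positive.periods),
                                  per=1e5)
        assert np.all(np.isfinite(surf["rates"]))
        assert np.all(surf["rates"] > 0)

    def test_bump_lifts_the_diagonal_by_the_peak_factor(self, sim_positive):
        spec = BasisSpec.from_table(sim_positive)
        f1 = cb.fit_ml(sim_positive, spec, CohortBump(1950.0, 4.0))
        f0 = cb.FitResult(theta=f1.theta, beta_c=None,
                          covariance=f1.covariance[:16, :16],
                          deviance_stat=np.nan, converged=True, n_iter=0,
                          bump=None, spec=spec)
        a = np.array([30.0])
        p = np.array([1980.0])  # p - a = 1950 = mu_c
        with_bump = cb.predict_surface(f1, a, p)["rates"]
        without = cb.predict_surface(f0, a, p)["rates"]
        factor = cb.peak_relative_risk(f1.beta_c, 4.0)
        np.testing.assert_allclose(with_bump, without * factor, rtol=1e-12)

    def test_far_off_grid_flags_extrapolation(self, small_table):
        f = cb.fit_ml(small_table, BasisSpec.from_table(small_table, 1, 1))
        surf = cb.predict_surface(f, [120.0], [2100.0])
        assert surf["extrapolated"]
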