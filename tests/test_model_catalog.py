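import dataclasses
from collections import Counter

import numpy as np
import pytest

import hale_ensemble as he
from hale_ensemble.model_catalog import _spec

from conftest import SMALL_AGES, make_common_drift_series


class TestCatalog:
    def test_has_21_models_with_stated_family_counts(self):
        specs = he.catalog()
        assert len(specs) == 21
        assert [s.id for s in specs] == list(range(1, 22))
        counts = Counter(s.family for s in specs)
        assert counts["age_time"] == 2
        assert counts["weighted_age_time"] + counts["weighted_age_time_cohort"] == 4
        assert counts["piecewise"] == 8
        assert counts["age_time_cohort"] == 2
        assert counts["lee_carter"] == 5

    def test_catalog_is_deterministic(self):
        assert he.catalog() == he.catalog()


class TestFit:
    def test_noiseless_linear_recovers_per_age_drift(self, noiseless_linear_panel):
        panel = noiseless_linear_panel
        spec = he.catalog()[1]  # age-time, per-age drift
        for key, truth in panel.truth.items():
            series = he.StratumSeries.from_panel(panel, *key)
            fit = he.fit(spec, series)
            n_ages = series.ages.size
            slopes = fit.params["coef"][n_ages: 2 * n_ages]
            assert np.max(np.abs(slopes - truth.drift)) < 1e-6

    def test_age_time_matches_independent_ols_oracle(self):
        # 3 ages x 10 years with noise; independent oracle assembled from the
        # normal equations via statsmodels OLS on the same design.
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        ages = np.array([0.0, 5.0, 10.0])
        years = np.arange(2000, 2010)
        values = (70 - 0.9 * ages)[:, None] + 0.3 * (years - years.mean())[None, :]
        values = values + rng.normal(0, 0.5, size=values.shape)
        series = he.StratumSeries(location="X", sex="male", ages=ages,
                                  years=years, values=values)
        spec = he.catalog()[1]
        fit = he.fit(spec, series)

        tbar = years.mean()
        X = []
        y = []
        for ai in range(3):
            for t, v in zip(years, values[ai]):
                row = np.zeros(6)
                row[ai] = 1.0
                row[3 + ai] = t - tbar
                X.append(row)
                y.append(v)
        oracle = sm.OLS(np.array(y), np.array(X)).fit()
        assert np.allclose(fit.params["coef"], oracle.params, atol=1e-8)

    def test_lee_carter_recovers_rank_one_structure(self):
        ages = np.arange(0.0, 40.0, 5.0)
        years = np.arange(1990, 2010)
        alpha = 70.0 - 0.7 * ages
        beta = np.linspace(0.2, 0.05, ages.size)
        beta = beta / beta.sum()
        k = np.linspace(4.0, -4.0, years.size) ** 3 / 10
        k = k - k.mean()
        values = alpha[:, None] + np.outer(beta, k)
        series = he.StratumSeries(location="X", sex="male", ages=ages,
                                  years=years, values=values)
        fit = he.fit(_spec(17, "lee_carter", "classic", variant="classic"), series)
        assert np.max(np.abs(fit.params["alpha"] - alpha)) < 1e-6
        assert np.max(np.abs(fit.params["beta"] - beta)) < 1e-6
        assert np.max(np.abs(fit.params["k"] - k)) < 1e-6

    def test_weighted_with_rho_one_reproduces_unweighted(self, noisy_series):
        unweighted = he.fit(he.catalog()[1], noisy_series)
        weighted = he.fit(
            _spec(99, "weighted_age_time", "rho=1", drift="per_age", rho=1.0),
            noisy_series,
        )
        assert np.allclose(unweighted.params["coef"], weighted.params["coef"],
                           atol=1e-10)

    def test_piecewise_zero_knots_reproduces_common_drift_age_time(self, noisy_series):
        base = he.fit(he.catalog()[0], noisy_series)  # common drift
        pw = he.fit(
            _spec(98, "piecewise", "0 knots", cohort=False, n_knots=0,
                  knot_rule="fixed", diff_order=1),
            noisy_series,
        )
        assert np.allclose(base.params["coef"], pw.params["coef"], atol=1e-10)

    def test_insufficient_history_raises(self, noisy_series):
        with pytest.raises(he.InsufficientHistoryError, match="insufficient history"):
            he.fit(he.catalog()[0], noisy_series, train_window=(2015, 2019))

    def test_constant_series_with_cohort_term_still_fits(self):
        ages = np.asarray(SMALL_AGES, dtype=float)
        years = np.arange(1990, 2010)
        values = np.tile((70.0 - 0.8 * ages)[:, None], (1, years.size))
        series = he.StratumSeries(location="X", sex="male", ages=ages,
                                  years=years, values=values)
        fit = he.fit(he.catalog()[14], series)  # age-time-cohort RW1
        assert np.all(np.isfinite(fit.params["coef"]))


class TestProject:
    def test_zero_uncertainty_draws_equal_deterministic_extrapolation(self):
        series = make_common_drift_series(np.random.default_rng(1), noise_sd=0.3)
        fit = he.fit(he.catalog()[1], series)
        fit.sigma2 = 0.0
        draws = he.project(fit, 5, 50, seed=3)
        assert np.allclose(draws.draws, draws.draws[0][None], atol=1e-12)
        slope = fit.params["coef"][series.ages.size]
        expected_last = (
            fit.params["coef"][0]
            + slope * (draws.years[-1] - fit.params["tbar"])
        )
        assert draws.draws[0, 0, -1] == pytest.approx(expected_last, abs=1e-9)

    def test_rng_contract(self, noisy_series):
        fit = he.fit(he.catalog()[16], noisy_series)
        a = he.project(fit, 5, 40, seed=9)
        b = he.project(fit, 5, 40, seed=9)
        c = he.project(fit, 5, 40, seed=10)
        assert np.array_equal(a.draws, b.draws)
        assert not np.array_equal(a.draws, c.draws)

    def test_all_models_produce_bounded_finite_draws(self, noisy_series):
        for spec in he.catalog():
            draws = he.project(he.fit(spec, noisy_series), 11, 60, seed=spec.id)
            assert np.all(np.isfinite(draws.draws))
            assert draws.draws.min() >= 0.0
            assert draws.draws.max() <= noisy_series.omega
            assert draws.draws.shape == (60, noisy_series.ages.size, 11)

    def test_invalid_arguments_rejected(self, noisy_series):
        fit = he.fit(he.catalog()[0], noisy_series)
        with pytest.raises(ValueError):
            he.project(fit, 0, 10, seed=1)
        with pytest.raises(ValueError):
            he.project(fit, 5, 0, seed=1)


def non_cohort_specs():
    keep = []
    for s in he.catalog():
        if s.family in ("weighted_age_time_cohort", "age_time_cohort"):
            continue
        if s.family == "piecewise" and s.opt("cohort"):
            continue
        if s.family == "lee_carter" and s.opt("variant") == "age_cohort":
            continue
        keep.append(s)
    return keep


@pytest.mark.parametrize("spec", non_cohort_specs(), ids=lambda s: s.name)
def test_non_cohort_families_converge_to_true_line(spec):
    """On noiseless common-drift linear truth, every non-cohort model's
    median projection matches the continued line at an 11-year horizon."""
    series = make_common_drift_series(np.random.default_rng(0), noise_sd=0.0)
    fit = he.fit(spec, series)
    draws = he.project(fit, 11, 200, seed=1)
    truth = (65.0 - 0.8 * series.ages)[:, None] + 0.25 * (
        draws.years - series.years.mean()
    )[None, :]
    assert np.max(np.abs(draws.median() - truth)) < 0.05


def test_coverage_of_noiseless_truth_on_replicate_panels():
    """Empirical 95%-interval coverage under a correctly specified model:
    replicate small iid-noise linear panels, project 11 years ahead, and
    count how often the interval covers the noiseless truth at birth."""
    spec = he.catalog()[1]
    hits = 0
    n_rep = 200
    for rep in range(n_rep):
        cfg = he.PanelConfig(n_countries=1, ages=SMALL_AGES, noise_sd=0.3,
                             ar1_rho=0.0, seed=10_000 + rep)
        panel = he.generate_panel(cfg)
        truth = panel.truth[("C001", "female")]
        series = he.StratumSeries.from_panel(panel, "C001", "female")
        draws = he.project(he.fit(spec, series), 11, 2000, seed=rep)
        lo, hi = np.percentile(draws.at_age(0.0)[:, -1], [2.5, 97.5])
        target = truth.true_values([int(draws.years[-1])])[0, 0]
        hits += int(lo <= target <= hi)
    assert 0.91 * n_rep <= hits <= 0.99 * n_rep
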