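import itertools

import numpy as np
import pandas as pd
import pytest

from ehr_lifegap.rate_model import (FitError, adjusted_rate_ratio,
                                    fit_poisson_quadratic, predict_rates,
                                    standardised_mortality_ratio)


def strata_frame(ages, deaths, person_years, sex="male", group="comparison"):
    return pd.DataFrame({"group": group, "sex": sex, "age": ages,
                         "deaths": deaths, "person_years": person_years})


def pois_loglik(beta, ages, deaths, py):
    eta = beta[0] + beta[1] * ages + beta[2] * ages ** 2 + np.log(py)
    return float(np.sum(deaths * eta - np.exp(eta)))


class TestFitPoissonQuadratic:
    def test_exact_recovery_when_counts_equal_expectations(self):
        # deaths = exp(c) * py exactly, with flat truth (b1 = b2 = 0):
        # the score vanishes at the truth, so the MLE is exact
        ages = np.arange(20, 90)
        py = np.full(ages.size, 40.0)
        c = np.log(0.015)
        d = np.exp(c) * py
        fit = fit_poisson_quadratic(strata_frame(ages, d, py))
        assert fit.coefficients == pytest.approx([c, 0.0, 0.0], abs=1e-8)

    def test_likelihood_dominates_surrounding_grid(self):
        ages = np.array([20.0, 35.0, 50.0, 70.0, 90.0])
        deaths = np.array([2, 1, 4, 9, 7])
        py = np.array([500.0, 400.0, 300.0, 150.0, 40.0])
        fit = fit_poisson_quadratic(strata_frame(ages, deaths, py))
        best = pois_loglik(fit.coefficients, ages, deaths, py)
        b0, b1, b2 = fit.coefficients
        for db0, db1, db2 in itertools.product(np.linspace(-0.5, 0.5, 5),
                                               np.linspace(-0.02, 0.02, 5),
                                               np.linspace(-2e-4, 2e-4, 5)):
            other = pois_loglik((b0 + db0, b1 + db1, b2 + db2),
                                ages, deaths, py)
            assert other <= best + 1e-9

    def test_aggregation_invariance_of_fit(self):
        """Splitting a stratum into pieces with the same totals leaves the
        MLE and its maximised likelihood unchanged (Poisson additivity)."""
        ages = np.arange(30, 80)
        rng = np.random.default_rng(3)
        py = rng.uniform(50, 150, ages.size)
        deaths = rng.poisson(np.exp(-9 + 0.08 * ages) * py)
        coarse = strata_frame(ages, deaths, py)
        # split every stratum 30/70 with deaths allocated proportionally in
        # expectation -- identical sufficient statistics by construction
        fine = pd.concat([
            strata_frame(ages, deaths * 0.3, py * 0.3),
            strata_frame(ages, deaths * 0.7, py * 0.7),
        ], ignore_index=True)
        f1 = fit_poisson_quadratic(coarse)
        f2 = fit_poisson_quadratic(fine)
        assert f1.coefficients == pytest.approx(f2.coefficients, abs=1e-7)

    def test_simulation_recovery_within_3se(self):
        truth = np.array([-10.0, 0.11, -2e-4])
        ages = np.arange(18, 101)
        py = np.full(ages.size, 5e4)
        rng = np.random.default_rng(11)
        lam = np.exp(truth[0] + truth[1] * ages + truth[2] * ages ** 2) * py
        fit = fit_poisson_quadratic(strata_frame(ages, rng.poisson(lam), py))
        se = np.sqrt(np.diag(fit.covariance))
        assert np.all(np.abs(fit.coefficients - truth) < 3 * se)

    def test_covariance_symmetric_psd_and_score_zero(self, strata):
        sub = strata[(strata.group == "comparison") & (strata.sex == "male")]
        sub = sub.groupby("age", as_index=False)[
            ["deaths", "person_years"]].sum()
        fit = fit_poisson_quadratic(sub)
        cov = fit.covariance
        assert np.allclose(cov, cov.T)
        assert np.linalg.eigvalsh(cov).min() >= -1e-12
        # score at the optimum (natural scale)
        a = sub["age"].to_numpy(float)
        X = np.column_stack([np.ones_like(a), a, a * a])
        mu = np.exp(X @ fit.coefficients) * sub["person_years"].to_numpy()
        score = X.T @ (sub["deaths"].to_numpy() - mu)
        assert np.max(np.abs(score / np.maximum(np.abs(X).max(0), 1))) < 1e-4

    def test_all_zero_deaths_raises(self):
        ages = np.arange(20, 40)
        with pytest.raises(FitError, match="zero deaths"):
            fit_poisson_quadratic(strata_frame(ages, np.zeros(ages.size),
                                               np.full(ages.size, 10.0)))

    def test_too_few_strata_raises(self):
        with pytest.raises(FitError, match="3 strata"):
            fit_poisson_quadratic(strata_frame([50, 60], [1, 2], [10.0, 10.0]))


class TestPredictRates:
    def test_flat_coefficients_give_constant_rate(self):
        from ehr_lifegap.rate_model import RateModelFit
        fit = RateModelFit(np.array([np.log(0.01), 0.0, 0.0]), np.zeros((3, 3)),
                           0.0, 10)
        assert predict_rates(fit, np.arange(18, 101)) == pytest.approx(
            np.full(83, 0.01))

    def test_monotone_when_vertex_below_range(self):
        from ehr_lifegap.rate_model import RateModelFit
        b2 = 1e-3
        b1 = -2 * b2 * 10.0  # vertex at age 10 < 18
        fit = RateModelFit(np.array([-8.0, b1, b2]), np.zeros((3, 3)), 0.0, 10)
        r = predict_rates(fit, np.arange(18, 101))
        assert (np.diff(r) > 0).all()

    def test_matches_direct_exponential_evaluation(self):
        from ehr_lifegap.rate_model import RateModelFit
        b = np.array([-9.5, 0.07, 1e-4])
        fit = RateModelFit(b, np.zeros((3, 3)), 0.0, 10)
        ages = np.arange(18, 101, dtype=float)
        direct = np.array([np.exp(b[0] + b[1] * a + b[2] * a * a)
                           for a in ages])
        assert predict_rates(fit, ages) == pytest.approx(direct, rel=1e-12)


class TestSMR:
    def test_group_compared_with_itself_is_exactly_one(self, strata):
        sub = strata[strata.group == "comparison"]
        smr = standardised_mortality_ratio(sub, sub)
        assert smr.estimate == pytest.approx(1.0, abs=1e-12)

    def test_single_stratum_hand_computation(self):
        exposed = strata_frame([50], [2], [100.0], group="exposed_no_id")
        comparison = strata_frame([50], [10], [1000.0])
        smr = standardised_mortality_ratio(exposed, comparison)
        # E = 0.01 * 100 = 1, O = 2
        assert smr.detail["expected"] == pytest.approx(1.0)
        assert smr.estimate == pytest.approx(2.0)
        assert smr.ci_low < 2.0 < smr.ci_high

    def test_uncovered_exposed_cells_are_dropped_and_reported(self):
        exposed = strata_frame([50, 51], [2, 1], [100.0, 50.0],
                               group="exposed_no_id")
        comparison = strata_frame([50], [10], [1000.0])
        smr = standardised_mortality_ratio(exposed, comparison)
        assert smr.detail["dropped_cells"] == 1
        assert smr.detail["dropped_person_years"] == pytest.approx(50.0)
        assert smr.detail["observed"] == pytest.approx(2.0)

    def test_zero_expected_raises(self):
        exposed = strata_frame([50], [1], [10.0], group="exposed_no_id")
        comparison = strata_frame([50], [0], [1000.0])
        with pytest.raises(ValueError, match="xpected"):
            standardised_mortality_ratio(exposed, comparison)

    def test_byar_interval_matches_direct_formula(self):
        exposed = strata_frame([50], [9], [100.0], group="exposed_no_id")
        comparison = strata_frame([50], [30], [1000.0])
        smr = standardised_mortality_ratio(exposed, comparison)
        z = 1.959963984540054
        o = 9.0
        lo = o * (1 - 1 / (9 * o) - z / (3 * np.sqrt(o))) ** 3
        hi = (o + 1) * (1 - 1 / (9 * (o + 1)) + z / (3 * np.sqrt(o + 1))) ** 3
        e = 0.03 * 100
        assert smr.ci_low == pytest.approx(lo / e)
        assert smr.ci_high == pytest.approx(hi / e)


class TestAdjustedRateRatio:
    @staticmethod
    def _two_group_strata(rr, cov_flag_effect=None, seed=0):
        """Poisson strata for comparison + exposed, optionally with the whole
        excess flowing through one covariate flag."""
        rng = np.random.default_rng(seed)
        ages = np.arange(20, 90)
        rows = []
        for group, cov in (("comparison", 0), ("exposed_no_id", 1)):
            py = np.full(ages.size, 3000.0)
            base = np.exp(-9.5 + 0.085 * ages)
            if cov_flag_effect is None:
                lam = base * (rr if group != "comparison" else 1.0)
                rows.append(strata_frame(ages, rng.poisson(lam * py), py,
                                         group=group).assign(cov_epilepsy=0))
            else:
                # exposed carry the flag; the flag carries the excess
                lam = base * (cov_flag_effect if cov == 1 else 1.0)
                rows.append(strata_frame(ages, rng.poisson(lam * py), py,
                                         group=group).assign(cov_epilepsy=cov))
        return pd.concat(rows, ignore_index=True)

    def test_all_zero_covariates_equal_unadjusted_estimate(self):
        strata = self._two_group_strata(rr=1.8)
        adj = adjusted_rate_ratio(strata, covariates=("cov_epilepsy",))
        unadj = adjusted_rate_ratio(strata)
        assert adj.estimate == pytest.approx(unadj.estimate, rel=1e-10)
        assert adj.covariates == ()  # vacuous column dropped

    def test_direct_effect_recovered_within_ci(self):
        strata = self._two_group_strata(rr=1.5, seed=4)
        est = adjusted_rate_ratio(strata)
        assert est.ci_low < 1.5 < est.ci_high
        assert est.estimate == pytest.approx(1.5, rel=0.1)

    @staticmethod
    def _mediated_strata(direct_rr, flag_hr, prev_exposed, prev_comparison,
                         seed=0):
        """Strata split by group x covariate pattern: the flag multiplies
        the hazard by ``flag_hr`` and is commoner among the exposed."""
        rng = np.random.default_rng(seed)
        ages = np.arange(20, 90)
        rows = []
        for group, prev, grr in (("comparison", prev_comparison, 1.0),
                                 ("exposed_no_id", prev_exposed, direct_rr)):
            for flag in (0, 1):
                py = np.full(ages.size, 3000.0) * (prev if flag else 1 - prev)
                lam = np.exp(-9.5 + 0.085 * ages) * grr * (flag_hr if flag
                                                           else 1.0)
                rows.append(strata_frame(ages, rng.poisson(lam * py), py,
                                         group=group).assign(cov_epilepsy=flag))
        return pd.concat(rows, ignore_index=True)

    def test_excess_through_comorbidity_vanishes_after_adjustment(self):
        strata = self._mediated_strata(direct_rr=1.0, flag_hr=3.0,
                                       prev_exposed=0.6, prev_comparison=0.05,
                                       seed=8)
        unadj = adjusted_rate_ratio(strata)
        adj = adjusted_rate_ratio(strata, covariates=("cov_epilepsy",))
        assert unadj.estimate > 1.4  # marginal excess from the comorbidity
        assert adj.ci_low < 1.0 < adj.ci_high
        assert adj.estimate == pytest.approx(1.0, abs=0.1)

    def test_direct_plus_mediated_recovers_direct_effect(self):
        strata = self._mediated_strata(direct_rr=1.5, flag_hr=2.0,
                                       prev_exposed=0.5, prev_comparison=0.1,
                                       seed=12)
        adj = adjusted_rate_ratio(strata, covariates=("cov_epilepsy",))
        assert adj.ci_low < 1.5 < adj.ci_high

    def test_collinear_design_raises(self):
        strata = self._two_group_strata(rr=None, cov_flag_effect=2.0, seed=8)
        # cov_epilepsy == exposure indicator exactly -> singular design
        with pytest.raises(FitError):
            adjusted_rate_ratio(strata, covariates=("cov_epilepsy",))

    def test_requires_both_groups(self):
        strata = strata_frame(np.arange(20, 40), np.ones(20),
                              np.full(20, 100.0))
        with pytest.raises(ValueError, match="exposed and comparison"):
            adjusted_rate_ratio(strata)
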