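"""Simulation-based validation studies with known ground truth.

Every study here generates synthetic cohorts whose mortality mechanism is
known in closed form, pushes them through the estimation pipeline, and
measures how well the pipeline recovers the truth: life expectancy at 18
under calibrated hazards (80 years for men, 83 for women in the comparison
group), a group hazard ratio of 2, nominal coverage of the SMR and
simulated life-expectancy intervals, and a null (hazard ratio 1) case.

Study conditions, chosen once:

* the full-scale recovery run uses a 200,000-person population with 5%
  exposure-type prevalence and no deregistration, so the comparison groups
  carry several thousand deaths per sex and the Monte-Carlo error on life
  expectancy (~0.3 years) is small against the 0.5-year check;
* coverage replicates use rare exposure in large practice pools (the regime
  of the real data) so matched comparisons are rarely reused across sets;
* comorbidity hazard ratios are set to 1 in all truth-recovery studies so
  the marginal group rate ratio equals the configured hazard ratio exactly.
"""

from __future__ import annotations

import numpy as np

from .cohort_builder import build_cohort
from .life_table import build_life_table, simulate_ci
from .persontime import aggregate_strata
from .rate_model import (FitError, fit_poisson_quadratic, predict_rates,
                         standardised_mortality_ratio)
from .synthetic_cohort import (CONDITIONS, SimulationConfig,
                               gm_central_rates, generate_population)

__all__ = [
    "GM_DEFAULT", "MALE_HR",
    "truth_e18",
    "recovery_config", "end_to_end_recovery",
    "smr_coverage_study", "e18_ci_coverage_study",
    "wald_coverage_study", "null_yll_study",
]

#: default Gompertz-Makeham parameters (lambda, alpha, beta), calibrated so
#: comparison-group total life expectancy at 18 is 83.0 for women
GM_DEFAULT = (5e-5, 2.8831907232731626e-05, 0.09)
#: male hazard multiplier calibrated to give 80.0 for men
MALE_HR = 1.3111530017961122

AGES = np.arange(18, 101)


def truth_e18(rate_multiplier: float = 1.0, gm=GM_DEFAULT) -> float:
    """Ground-truth total life expectancy at 18: the exact central death
    rates of the generator's hazard pushed through the same life table."""
    return build_life_table(gm_central_rates(AGES, gm, rate_multiplier)).e18_total


def _neutral(group_hr: float) -> dict:
    return dict(
        deregistration_rate=0.0,
        group_hazard_ratios={"exposed_no_id": group_hr,
                             "exposed_with_id": group_hr, "comparison": 1.0},
        comorbidity_hazard_ratios={c: 1.0 for c in CONDITIONS},
    )


def recovery_config(seed: int, *, n_practices: int = 20,
                    persons_per_practice: int = 10_000,
                    exposure_prevalence: float = 0.05,
                    group_hr: float = 2.0) -> SimulationConfig:
    """Well-powered truth-recovery conditions (see module docstring)."""
    return SimulationConfig(
        n_practices=n_practices, persons_per_practice=persons_per_practice,
        exposure_prevalence=exposure_prevalence, seed=seed,
        **_neutral(group_hr))


def _comparison_fits(strata, sexes=("male", "female")):
    fits = {}
    for sex in sexes:
        for side, mask in (("comparison", strata["group"] == "comparison"),
                           ("exposed", strata["group"] != "comparison")):
            sub = (strata.loc[mask & (strata["sex"] == sex)]
                   .groupby("age", as_index=False)[
                       ["deaths", "person_years"]].sum())
            fits[(side, sex)] = fit_poisson_quadratic(sub,
                                                      label=f"{side} {sex}")
    return fits


def end_to_end_recovery(seed: int, n_sim: int = 2000) -> dict:
    """Full pipeline at scale under known truth.

    Returns SMRs per cohort (truth 2.0), comparison-group life expectancy
    per sex (truth 80.0 / 83.0), exposed life expectancy and years of life
    lost per sex with simulation intervals.
    """
    cfg = recovery_config(seed)
    pop = generate_population(cfg)
    cohort = build_cohort(pop, k=cfg.comparison_ratio, seed=seed,
                          study_start=cfg.study_start, study_end=cfg.study_end)
    strata = aggregate_strata(cohort)
    out = {"n_population": len(pop), "n_intervals": len(cohort.intervals)}
    for coh in ("no_id", "with_id"):
        sub = strata.loc[strata["cohort"] == coh]
        smr = standardised_mortality_ratio(sub[sub.group != "comparison"],
                                           sub[sub.group == "comparison"])
        out[f"smr_{coh}"] = smr
    fits = _comparison_fits(strata)
    for sex in ("male", "female"):
        est = simulate_ci(fits[("exposed", sex)], fits[("comparison", sex)],
                          n_sim=n_sim, seed=seed)
        out[f"e18_comparison_{sex}"] = est["comparison"]
        out[f"e18_exposed_{sex}"] = est["exposed"]
        out[f"yll_{sex}"] = est["yll"]
    return out


def smr_coverage_study(n_reps: int = 200, seed: int = 0) -> dict:
    """Fraction of replicates whose SMR interval covers the true hazard
    ratio of 2.  Rare exposure in large pools keeps matched comparisons
    nearly disjoint across sets, the regime the interval assumes."""
    rng_seeds = np.random.SeedSequence(seed).generate_state(2 * n_reps) % (2**31)
    covered = 0
    observed = []
    estimates = []
    for rep in range(n_reps):
        cfg = recovery_config(int(rng_seeds[rep]), n_practices=4,
                              persons_per_practice=10_000,
                              exposure_prevalence=0.004)
        pop = generate_population(cfg)
        cohort = build_cohort(pop, k=10, seed=int(rng_seeds[n_reps + rep]))
        strata = aggregate_strata(cohort)
        sub = strata.loc[strata["cohort"] == "no_id"]
        smr = standardised_mortality_ratio(sub[sub.group != "comparison"],
                                           sub[sub.group == "comparison"])
        covered += smr.ci_low <= 2.0 <= smr.ci_high
        observed.append(smr.detail["observed"])
        estimates.append(smr.estimate)
    return {"coverage": covered / n_reps, "n_reps": n_reps,
            "mean_observed_deaths": float(np.mean(observed)),
            "mean_smr": float(np.mean(estimates))}


def e18_ci_coverage_study(n_reps: int = 200, seed: int = 0,
                          n_sim: int = 800) -> dict:
    """Fraction of replicates whose simulated life-expectancy interval for
    comparison men covers the true 80.0 years (discretisation-matched)."""
    truth = truth_e18(MALE_HR)
    rng_seeds = np.random.SeedSequence(seed + 1).generate_state(2 * n_reps) % (2**31)
    covered = n_ok = failures = 0
    for rep in range(n_reps):
        cfg = recovery_config(int(rng_seeds[rep]), n_practices=2,
                              persons_per_practice=6_000,
                              exposure_prevalence=0.02)
        pop = generate_population(cfg)
        cohort = build_cohort(pop, k=10, seed=int(rng_seeds[n_reps + rep]))
        strata = aggregate_strata(cohort)
        try:
            fits = _comparison_fits(strata, sexes=("male",))
            est = simulate_ci(fits[("exposed", "male")],
                              fits[("comparison", "male")],
                              n_sim=n_sim, seed=int(rng_seeds[rep]))
        except FitError:
            failures += 1
            continue
        n_ok += 1
        covered += est["comparison"].ci_low <= truth <= est["comparison"].ci_high
    return {"coverage": covered / max(n_ok, 1), "n_reps": n_reps,
            "n_ok": n_ok, "failures": failures, "truth": truth}


def wald_coverage_study(n_reps: int = 500, seed: int = 0,
                        truth=(-10.5, 0.11, -3e-4),
                        person_years: float = 5_000.0) -> dict:
    """Coverage of the 95% Wald intervals of the log-quadratic Poisson fit
    when the data really are Poisson from a quadratic log-rate."""
    import pandas as pd

    truth = np.asarray(truth, float)
    rng = np.random.default_rng(seed)
    lam = np.exp(truth[0] + truth[1] * AGES + truth[2] * AGES ** 2) * person_years
    z = 1.959963984540054
    covered = np.zeros(3)
    for _ in range(n_reps):
        deaths = rng.poisson(lam)
        strata = pd.DataFrame({"age": AGES, "deaths": deaths,
                               "person_years": person_years})
        fit = fit_poisson_quadratic(strata)
        se = np.sqrt(np.diag(fit.covariance))
        covered += np.abs(fit.coefficients - truth) <= z * se
    return {"coverage": (covered / n_reps).tolist(), "n_reps": n_reps}


def null_yll_study(n_seeds: int = 8, seed: int = 0) -> dict:
    """Years of life lost under a group hazard ratio of exactly 1:
    point estimates should scatter around zero."""
    rng_seeds = np.random.SeedSequence(seed + 2).generate_state(n_seeds) % (2**31)
    ylls = []
    failures = 0
    for s in rng_seeds:
        cfg = recovery_config(int(s), n_practices=2,
                              persons_per_practice=10_000,
                              exposure_prevalence=0.05, group_hr=1.0)
        pop = generate_population(cfg)
        cohort = build_cohort(pop, k=10, seed=int(s) + 1)
        strata = aggregate_strata(cohort)
        try:
            fits = _comparison_fits(strata, sexes=("male",))
        except FitError:
            failures += 1
            continue
        lt_e = build_life_table(predict_rates(fits[("exposed", "male")], AGES))
        lt_c = build_life_table(predict_rates(fits[("comparison", "male")], AGES))
        ylls.append(lt_c.e18_total - lt_e.e18_total)
    return {"yll_points": ylls, "mean_yll": float(np.mean(ylls)),
            "failures": failures}
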