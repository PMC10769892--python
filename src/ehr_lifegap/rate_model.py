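"""Poisson models of age-specific mortality and mortality rate ratios.

The smoothing model is log-quadratic in age: deaths in stratum (age a,
person-years t) are Poisson with mean ``exp(b0 + b1*a + b2*a^2) * t``.
Using a model rather than raw stratum rates borrows strength across ages,
which matters because single-year strata are sparse.  Internally age is
centred at 60 and scaled by 1/10 for conditioning; coefficients and their
covariance are reported on the natural age scale.

Two rate-ratio estimators are provided: indirect standardisation (SMR with
Byar confidence limits) and a model-based group effect from a joint Poisson
regression, optionally adjusted for entry covariates (Wald limits).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RateModelFit",
    "RateRatioEstimate",
    "fit_poisson_quadratic",
    "predict_rates",
    "standardised_mortality_ratio",
    "adjusted_rate_ratio",
]

_AGE_CENTER = 60.0
_AGE_SCALE = 10.0

# natural-scale coefs = _UNSCALE @ scaled coefs, from expanding
# b0 + b1*(a-60)/10 + b2*((a-60)/10)^2 in powers of a
_UNSCALE = np.array([
    [1.0, -_AGE_CENTER / _AGE_SCALE, (_AGE_CENTER / _AGE_SCALE) ** 2],
    [0.0, 1.0 / _AGE_SCALE, -2.0 * _AGE_CENTER / _AGE_SCALE ** 2],
    [0.0, 0.0, 1.0 / _AGE_SCALE ** 2],
])


class FitError(RuntimeError):
    """Raised when a Poisson fit cannot be computed or did not converge."""


@dataclass
class RateModelFit:
    """A fitted log-quadratic mortality curve.

    ``coefficients`` and ``covariance`` are on the natural age scale
    (intercept, age, age^2, then any extra covariates in ``extra_names``).
    """

    coefficients: np.ndarray
    covariance: np.ndarray
    deviance: float
    n_strata: int
    label: str = ""
    extra_names: tuple = ()
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "coefficients": list(map(float, self.coefficients)),
            "covariance": [list(map(float, row)) for row in self.covariance],
            "deviance": float(self.deviance),
            "n_strata": int(self.n_strata),
            "extra_names": list(self.extra_names),
            "converged": bool(self.converged),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RateModelFit":
        return cls(coefficients=np.asarray(d["coefficients"], float),
                   covariance=np.asarray(d["covariance"], float),
                   deviance=d["deviance"], n_strata=d["n_strata"],
                   label=d.get("label", ""),
                   extra_names=tuple(d.get("extra_names", ())),
                   converged=d.get("converged", True))


@dataclass
class RateRatioEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    method: str  # 'standardised' or 'model_adjusted'
    covariates: tuple = ()
    detail: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"estimate": self.estimate, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "method": self.method,
                "covariates": list(self.covariates),
                **{k: v for k, v in self.detail.items()}}


def _design(ages: np.ndarray, extra: np.ndarray | None = None) -> np.ndarray:
    z = (np.asarray(ages, float) - _AGE_CENTER) / _AGE_SCALE
    X = np.column_stack([np.ones_like(z), z, z * z])
    if extra is not None and extra.size:
        X = np.column_stack([X, extra])
    return X


def _unscale(params: np.ndarray, cov: np.ndarray, n_extra: int):
    k = 3 + n_extra
    M = np.eye(k)
    M[:3, :3] = _UNSCALE
    return M @ params, M @ cov @ M.T


def fit_poisson_quadratic(strata: pd.DataFrame, covariates=(),
                          label: str = "") -> RateModelFit:
    """Maximum-likelihood fit of the log-quadratic Poisson rate model.

    ``strata`` needs columns ``age``, ``deaths``, ``person_years``; rows
    with zero person-years are excluded (zero-death rows are valid data and
    kept).  ``covariates`` names additional indicator columns entering the
    linear predictor.  Fitting is iteratively reweighted least squares with
    an offset of log person-years.
    """
    covariates = tuple(covariates)
    d = strata.loc[strata["person_years"] > 0]
    if len(d) < 3:
        raise FitError("need at least 3 strata with positive person-years")
    if (d["deaths"] == 0).all():
        raise FitError(
            "all strata have zero deaths; the log-rate model is unbounded below "
            "(consider pooling strata or widening the data window)")
    extra = d[list(covariates)].to_numpy(float) if covariates else None
    X = _design(d["age"].to_numpy(), extra)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = [c for c in covariates
               if d[c].nunique() <= 1
               or np.linalg.matrix_rank(_design(d["age"].to_numpy(),
                                                d[[c]].to_numpy(float))) < 4]
        raise FitError(f"design matrix is singular (collinear columns: {bad})")
    model = sm.GLM(d["deaths"].to_numpy(float), X, family=sm.families.Poisson(),
                   offset=np.log(d["person_years"].to_numpy(float)))
    try:
        res = model.fit(maxiter=200, tol=1e-10)
    except Exception as exc:  # singular IRLS step, overflow, ...
        raise FitError(f"Poisson IRLS failed: {exc}") from exc
    if not res.converged:
        raise FitError(
            f"Poisson IRLS did not converge after {res.fit_history['iteration']} "
            f"iterations; deviance={res.deviance:.4g}")
    score = model.score(res.params)
    if np.max(np.abs(score)) > 1e-4 * max(1.0, float(d["deaths"].sum())):
        raise FitError(f"score not zero at optimum (max |score|={np.max(np.abs(score)):.3g})")
    coef, cov = _unscale(res.params, res.cov_params(), len(covariates))
    return RateModelFit(coefficients=coef, covariance=cov,
                        deviance=float(res.deviance), n_strata=len(d),
                        label=label, extra_names=covariates, converged=True)


def predict_rates(fit: RateModelFit, ages) -> np.ndarray:
    """Modelled mortality rate per person-year at each age (covariates at
    reference level zero)."""
    if not fit.converged:
        raise FitError("cannot predict from a non-converged fit")
    a = np.asarray(ages, float)
    b = fit.coefficients
    return np.exp(b[0] + b[1] * a + b[2] * a * a)


def _byar_ci(observed: float, alpha: float = 0.05):
    """Byar's approximation to the Poisson CI for an observed count."""
    z = stats.norm.ppf(1 - alpha / 2)
    o = float(observed)
    if o > 0:
        low = o * (1 - 1 / (9 * o) - z / (3 * np.sqrt(o))) ** 3
    else:
        low = 0.0
    op = o + 1
    high = op * (1 - 1 / (9 * op) + z / (3 * np.sqrt(op))) ** 3
    return low, high


def standardised_mortality_ratio(exposed_strata: pd.DataFrame,
                                 comparison_strata: pd.DataFrame,
                                 by=("sex", "age")) -> RateRatioEstimate:
    """Indirectly standardised mortality ratio.

    Expected deaths apply the comparison group's crude stratum rates to the
    exposed person-time, cell by cell over ``by`` (age and sex by default).
    Exposed cells with person-time but no comparison rate are dropped and
    counted in ``detail['dropped_cells']``.  95% CI by Byar's approximation
    on the observed count.
    """
    by = list(by)
    exp_g = (exposed_strata.groupby(by, as_index=False, observed=True)
             [["deaths", "person_years"]].sum())
    cmp_g = (comparison_strata.groupby(by, as_index=False, observed=True)
             [["deaths", "person_years"]].sum())
    cmp_g = cmp_g.loc[cmp_g["person_years"] > 0].copy()
    cmp_g["rate"] = cmp_g["deaths"] / cmp_g["person_years"]
    merged = exp_g.merge(cmp_g[by + ["rate"]], on=by, how="left")
    merged = merged.loc[merged["person_years"] > 0]
    covered = merged["rate"].notna()
    dropped = merged.loc[~covered]
    m = merged.loc[covered]
    expected = float((m["rate"] * m["person_years"]).sum())
    observed = float(m["deaths"].sum())
    if expected == 0:
        raise ValueError("expected deaths are zero; SMR undefined")
    smr = observed / expected
    lo, hi = _byar_ci(observed)
    return RateRatioEstimate(
        estimate=smr, ci_low=lo / expected, ci_high=hi / expected,
        method="standardised",
        detail={"observed": observed, "expected": expected,
                "dropped_cells": int(len(dropped)),
                "dropped_deaths": float(dropped["deaths"].sum()),
                "dropped_person_years": float(dropped["person_years"].sum())})


def adjusted_rate_ratio(strata: pd.DataFrame, covariates=(),
                        exposed_groups=("exposed_no_id", "exposed_with_id"),
                        alpha: float = 0.05) -> RateRatioEstimate:
    """Model-based mortality rate ratio for exposed vs comparison.

    Fits a joint Poisson model with an exposure indicator, quadratic age,
    a sex indicator when both sexes are present, and any ``covariates``
    (entry-frozen condition flags).  Returns the exponentiated exposure
    coefficient with Wald limits.
    """
    covariates = tuple(covariates)
    d = strata.loc[strata["person_years"] > 0].copy()
    d["_exposed"] = d["group"].isin(exposed_groups).astype(float)
    if d["_exposed"].nunique() < 2:
        raise ValueError("strata must contain both exposed and comparison groups")
    cols = ["_exposed"]
    if "sex" in d.columns and d["sex"].nunique() > 1:
        d["_male"] = (d["sex"] == "male").astype(float)
        cols.append("_male")
    # drop covariates with no variation (all-zero columns are vacuous and
    # would make the design singular)
    active = [c for c in covariates if c in d.columns and d[c].nunique() > 1]
    cols += active
    X = _design(d["age"].to_numpy(), d[cols].to_numpy(float))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError(f"design matrix singular; check columns {cols}")
    model = sm.GLM(d["deaths"].to_numpy(float), X, family=sm.families.Poisson(),
                   offset=np.log(d["person_years"].to_numpy(float)))
    res = model.fit(maxiter=200, tol=1e-10)
    if not res.converged or not np.all(np.isfinite(res.bse)):
        raise FitError("adjusted Poisson model did not converge "
                       f"(possible separation in {cols})")
    i = 3  # exposure indicator follows the three age terms
    z = stats.norm.ppf(1 - alpha / 2)
    b, se = res.params[i], res.bse[i]
    return RateRatioEstimate(
        estimate=float(np.exp(b)), ci_low=float(np.exp(b - z * se)),
        ci_high=float(np.exp(b + z * se)), method="model_adjusted",
        covariates=tuple(active),
        detail={"log_rr": float(b), "se_log_rr": float(se),
                "n_strata": int(len(d))})
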