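"""Period life tables, life expectancy at 18, and years of life lost.

Standard abridged-to-single-year period life table over ages 18..100 with
an open interval at 100, following the national-statistics convention:
deaths are assumed to fall mid-year within each closed age (a_x = 0.5), so
``q_x = m_x / (1 + 0.5 * m_x)``, and the open interval is closed under a
constant-hazard assumption, ``L_100 = l_100 / m_100``.  The headline figure
is total expected length of life for someone aged 18, i.e. ``18 + e_18``.

Confidence intervals are obtained by parametric simulation: coefficient
vectors are drawn from the fitted Poisson model's asymptotic normal
distribution, rates and a life table are rebuilt per draw, and percentile
intervals are read off the simulated life expectancies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rate_model import RateModelFit, predict_rates

__all__ = [
    "LifeTable",
    "LifeExpectancyEstimate",
    "build_life_table",
    "years_of_life_lost",
    "simulate_ci",
    "RADIX",
]

RADIX = 100_000.0


@dataclass
class LifeTable:
    """Columns ``age, m, q, l, d, L, T, e`` plus ``e18_total = 18 + e_18``."""

    table: pd.DataFrame
    e18_total: float

    @property
    def ages(self) -> np.ndarray:
        return self.table["age"].to_numpy()


def _e_from_m(m: np.ndarray, age_start: int, radix: float = RADIX):
    """Vectorised life-table engine.

    ``m`` has shape (..., n_ages); returns (q, l, d, L, T, e) each of the
    same shape, with remaining life expectancy ``e`` at every age.
    """
    m = np.asarray(m, float)
    q = m / (1.0 + 0.5 * m)
    q = np.minimum(q, 1.0)  # m > 2 would otherwise push q past one
    q[..., -1] = 1.0  # open interval: everyone dies
    # survivors: l_{x+1} = l_x (1 - q_x)
    surv = np.cumprod(1.0 - q[..., :-1], axis=-1)
    l = np.concatenate([np.full((*m.shape[:-1], 1), radix),
                        radix * surv], axis=-1)
    d = l * q
    L = l - 0.5 * d
    with np.errstate(divide="ignore", invalid="ignore"):
        L_open = np.where(m[..., -1] > 0, l[..., -1] / m[..., -1], np.nan)
    L = np.concatenate([L[..., :-1], L_open[..., None]], axis=-1)
    T = np.cumsum(L[..., ::-1], axis=-1)[..., ::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / l, 0.0)
    return q, l, d, L, T, e


def build_life_table(rates, age_start: int = 18, radix: float = RADIX) -> LifeTable:
    """Build a period life table from central mortality rates.

    ``rates`` is the sequence of m_x for consecutive single-year ages
    beginning at ``age_start``; the last element is the open-interval rate
    and must be positive.
    """
    m = np.asarray(rates, float)
    if m.ndim != 1 or m.size < 2:
        raise ValueError("rates must be a 1-d sequence of at least two ages")
    if np.any(m < 0) or np.any(~np.isfinite(m)):
        raise ValueError("all mortality rates must be finite and >= 0")
    if m[-1] <= 0:
        raise ValueError("rate at the open age interval must be > 0 "
                         "(the open interval is closed by L = l/m)")
    q, l, d, L, T, e = _e_from_m(m, age_start, radix)
    ages = np.arange(age_start, age_start + m.size)
    table = pd.DataFrame({"age": ages, "m": m, "q": q, "l": l, "d": d,
                          "L": L, "T": T, "e": e})
    return LifeTable(table=table, e18_total=float(age_start + e[0]))


def years_of_life_lost(lt_exposed: LifeTable, lt_comparison: LifeTable) -> float:
    """Difference in total life expectancy at 18, comparison minus exposed
    (positive when the exposed group dies earlier)."""
    if not np.array_equal(lt_exposed.ages, lt_comparison.ages):
        raise ValueError("life tables must cover the same age range")
    return float(lt_comparison.e18_total - lt_exposed.e18_total)


@dataclass
class LifeExpectancyEstimate:
    point: float
    ci_low: float
    ci_high: float
    n_simulations: int
    seed: int
    bracketed: bool = True  # False if the percentile interval misses the point
    label: str = ""

    def to_dict(self) -> dict:
        return {"label": self.label, "point": self.point, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "n_simulations": self.n_simulations,
                "seed": self.seed, "bracketed": self.bracketed}


def _check_psd(cov: np.ndarray, label: str) -> None:
    w = np.linalg.eigvalsh((cov + cov.T) / 2.0)
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise ValueError(f"covariance for {label} is not positive semi-definite "
                         f"(min eigenvalue {w.min():.3g})")


def _simulated_e18(fit: RateModelFit, ages: np.ndarray, n_sim: int,
                   rng: np.random.Generator) -> np.ndarray:
    cov = fit.covariance[:3, :3]
    _check_psd(cov, fit.label or "fit")
    draws = rng.multivariate_normal(fit.coefficients[:3], cov, size=n_sim,
                                    method="svd")
    # log-rate per draw per age; clip the exponent to dodge overflow on
    # extreme tail draws (such draws already imply immediate death)
    loglam = (draws[:, [0]] + draws[:, [1]] * ages[None, :]
              + draws[:, [2]] * ages[None, :] ** 2)
    m = np.exp(np.minimum(loglam, 50.0))
    m[:, -1] = np.maximum(m[:, -1], 1e-300)
    *_, e = _e_from_m(m, int(ages[0]))
    return ages[0] + e[:, 0]


def simulate_ci(fit_exposed: RateModelFit, fit_comparison: RateModelFit,
                n_sim: int = 10_000, seed: int = 0,
                ages=None, alpha: float = 0.05):
    """Simulation confidence intervals for life expectancy and YLL.

    Coefficients for the two groups are drawn independently from their
    asymptotic normal distributions; each draw is pushed through the life
    table.  Returns a dict with :class:`LifeExpectancyEstimate` entries
    ``exposed``, ``comparison`` and ``yll`` (years of life lost =
    comparison minus exposed).  Deterministic given ``seed``.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if ages is None:
        ages = np.arange(18, 101)
    ages = np.asarray(ages, float)
    rng = np.random.default_rng(seed)

    point_exp = build_life_table(predict_rates(fit_exposed, ages),
                                 int(ages[0])).e18_total
    point_cmp = build_life_table(predict_rates(fit_comparison, ages),
                                 int(ages[0])).e18_total

    sims_exp = _simulated_e18(fit_exposed, ages, n_sim, rng)
    sims_cmp = _simulated_e18(fit_comparison, ages, n_sim, rng)
    sims_yll = sims_cmp - sims_exp

    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)

    def estimate(point, sims, label):
        ci_low, ci_high = np.percentile(sims, [lo, hi])
        return LifeExpectancyEstimate(
            point=float(point), ci_low=float(ci_low), ci_high=float(ci_high),
            n_simulations=n_sim, seed=seed,
            bracketed=bool(ci_low <= point <= ci_high), label=label)

    return {
        "exposed": estimate(point_exp, sims_exp, "e18_total exposed"),
        "comparison": estimate(point_cmp, sims_cmp, "e18_total comparison"),
        "yll": estimate(point_cmp - point_exp, sims_yll, "years of life lost"),
    }
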