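"""Seeded synthetic primary-care populations with known mortality structure.

Real primary-care mortality cohorts cannot be redistributed, so this module
generates populations with the statistical structure the downstream analysis
assumes: a multi-practice adult population observed over a fixed study
window, a rare diagnosed exposure group, Gompertz–Makeham adult mortality
with group- and sex-specific hazard ratios, comorbidity flags that act
multiplicatively on the hazard, independent exponential deregistration, and
administrative censoring.

Because every hazard is known in closed form, the pipeline's estimates
(mortality ratios, life expectancy at 18, years of life lost) can be checked
against analytic truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
import yaml

from .dates import DAYS_PER_YEAR, as_days

__all__ = [
    "SimulationConfig",
    "GROUPS",
    "CONDITIONS",
    "generate_population",
    "sample_death_age",
    "write_population_csv",
    "read_population_csv",
    "gm_cumulative_hazard",
    "gm_survival",
    "gm_central_rates",
    "gm_life_expectancy_total",
]

GROUPS = ("exposed_no_id", "exposed_with_id", "comparison")

#: comorbidity conditions carried as onset-date columns (``como_<name>``)
CONDITIONS = (
    "epilepsy",
    "genetic",
    "mobility",
    "visual",
    "hearing",
    "adhd",
    "smi",
    "self_harm",
)

# Default per-group comorbidity prevalences, loosely following the pattern of
# UK primary-care autism cohorts: every condition commoner in the diagnosed
# groups, and commonest with co-occurring intellectual disability.
_DEFAULT_COMORBIDITY_PREV = {
    "epilepsy": {"comparison": 0.01, "exposed_no_id": 0.05, "exposed_with_id": 0.21},
    "genetic": {"comparison": 0.005, "exposed_no_id": 0.015, "exposed_with_id": 0.08},
    "mobility": {"comparison": 0.0025, "exposed_no_id": 0.01, "exposed_with_id": 0.04},
    "visual": {"comparison": 0.003, "exposed_no_id": 0.007, "exposed_with_id": 0.02},
    "hearing": {"comparison": 0.017, "exposed_no_id": 0.02, "exposed_with_id": 0.035},
    "adhd": {"comparison": 0.015, "exposed_no_id": 0.14, "exposed_with_id": 0.11},
    "smi": {"comparison": 0.005, "exposed_no_id": 0.055, "exposed_with_id": 0.11},
    "self_harm": {"comparison": 0.025, "exposed_no_id": 0.09, "exposed_with_id": 0.06},
}

# Hazard multipliers attached to each comorbidity flag.  These give the
# covariate-adjusted analysis something genuine to adjust for.
_DEFAULT_COMORBIDITY_HR = {
    "epilepsy": 2.0,
    "genetic": 3.0,
    "mobility": 2.0,
    "visual": 1.1,
    "hearing": 1.0,
    "adhd": 1.2,
    "smi": 1.6,
    "self_harm": 1.7,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic data-generating process.

    Mortality follows a Gompertz–Makeham hazard
    ``h(a) = lambda + alpha * exp(beta * a)`` (per year, age ``a`` in years),
    multiplied by the person's group hazard ratio, a sex hazard ratio for
    men, and the product of the hazard ratios of their comorbidity flags.
    The default Gompertz–Makeham parameters are calibrated so that the
    comparison group's total life expectancy at age 18 is 80 years for men
    and 83 for women.
    """

    n_practices: int = 20
    persons_per_practice: int = 10_000
    exposure_prevalence: float = 1.0 / 450.0
    comparison_ratio: int = 10
    study_start: date = date(1989, 1, 1)
    study_end: date = date(2019, 1, 16)
    makeham_lambda: float = 5e-5
    gompertz_alpha: float = 2.8831907232731626e-05
    gompertz_beta: float = 0.09
    group_hazard_ratios: dict = field(
        default_factory=lambda: {
            "exposed_no_id": 2.0,
            "exposed_with_id": 3.0,
            "comparison": 1.0,
        }
    )
    sex_hazard_ratio: float = 1.3111530017961122  # male vs female
    comorbidity_prevalences: dict = field(
        default_factory=lambda: {c: dict(p) for c, p in _DEFAULT_COMORBIDITY_PREV.items()}
    )
    comorbidity_hazard_ratios: dict = field(
        default_factory=lambda: dict(_DEFAULT_COMORBIDITY_HR)
    )
    deregistration_rate: float = 0.03  # per year
    possible_death_fraction: float = 0.02
    id_fraction: float = 0.27  # fraction of exposed with intellectual disability
    id_delay_fraction: float = 0.3  # of those, fraction whose ID is recorded later
    seed: int = 0

    def validate(self) -> None:
        """Raise :class:`ValueError` naming the first offending field."""
        if self.n_practices < 1:
            raise ValueError("n_practices must be >= 1")
        if self.persons_per_practice < 1:
            raise ValueError("persons_per_practice must be >= 1")
        for name in ("exposure_prevalence", "possible_death_fraction",
                     "id_fraction", "id_delay_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1]")
        for name in ("makeham_lambda", "gompertz_alpha"):
            if getattr(self, name) < 0 or not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite and >= 0")
        if self.makeham_lambda == 0 and self.gompertz_alpha == 0:
            raise ValueError("makeham_lambda and gompertz_alpha cannot both be 0")
        if not (np.isfinite(self.gompertz_beta) and self.gompertz_beta > 0):
            raise ValueError("gompertz_beta must be finite and > 0")
        if self.comparison_ratio < 1:
            raise ValueError("comparison_ratio must be >= 1 (k comparisons per exposed)")
        if self.sex_hazard_ratio <= 0:
            raise ValueError("sex_hazard_ratio must be > 0")
        for g in GROUPS:
            if g not in self.group_hazard_ratios:
                raise ValueError(f"group_hazard_ratios missing group '{g}'")
            if self.group_hazard_ratios[g] <= 0:
                raise ValueError(f"group_hazard_ratios['{g}'] must be > 0")
        for c, by_group in self.comorbidity_prevalences.items():
            if c not in CONDITIONS:
                raise ValueError(f"comorbidity_prevalences has unknown condition '{c}'")
            for g, p in by_group.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(
                        f"comorbidity_prevalences['{c}']['{g}'] must be in [0, 1]")
        for c, hr in self.comorbidity_hazard_ratios.items():
            if hr <= 0:
                raise ValueError(f"comorbidity_hazard_ratios['{c}'] must be > 0")
        if self.deregistration_rate < 0:
            raise ValueError("deregistration_rate must be >= 0")
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["study_start"] = self.study_start.isoformat()
        d["study_end"] = self.study_end.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for k in ("study_start", "study_end"):
            if k in d and isinstance(d[k], str):
                d[k] = date.fromisoformat(d[k])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def sample_death_age(birth_age, hazard_params, rate_multiplier, rng, size=None):
    """Draw age(s) at death from a Gompertz–Makeham hazard, conditional on
    survival to ``birth_age``.

    Parameters
    ----------
    birth_age : float or array
        Age (years) the person is known to have survived to.
    hazard_params : tuple (lambda, alpha, beta)
        Makeham constant, Gompertz level at age 0, log-hazard slope.
    rate_multiplier : float or array
        Proportional multiplier on the whole hazard (> 0).
    rng : numpy Generator
    size : optional output shape when the other arguments are scalars.

    Uses inverse-transform sampling of the cumulative hazard
    ``H(a) = lambda*a + (alpha/beta)*(exp(beta*a) - 1)``: draw a unit
    exponential ``E`` and solve ``mult * (H(a) - H(a0)) = E``.  The pure
    exponential (alpha = 0) and pure Gompertz (lambda = 0) cases have closed
    forms; the mixed case is solved by vectorised bisection, bracketed by
    the two closed-form solutions (each is an upper bound since dropping
    either hazard component only slows accumulation).
    """
    lam, alpha, beta = (float(x) for x in hazard_params)
    if not all(np.isfinite([lam, alpha, beta])):
        raise ValueError("hazard parameters must be finite")
    if lam < 0 or alpha < 0 or beta <= 0:
        raise ValueError("hazard parameters must be positive (lambda, alpha >= 0)")
    if lam == 0 and alpha == 0:
        raise ValueError("lambda and alpha cannot both be zero")
    mult = np.asarray(rate_multiplier, dtype=float)
    if np.any(~np.isfinite(mult)) or np.any(mult <= 0):
        raise ValueError("rate_multiplier must be finite and > 0")

    a0 = np.asarray(birth_age, dtype=float)
    if size is None:
        shape = np.broadcast_shapes(a0.shape, mult.shape)
    else:
        shape = (size,)
    u = rng.exponential(size=shape) / np.broadcast_to(mult, shape)
    a0 = np.broadcast_to(a0, shape)

    if alpha == 0.0:  # pure Makeham/exponential
        t = u / lam
    elif lam == 0.0:  # pure Gompertz, closed form
        t = np.log1p(u * beta / (alpha * np.exp(beta * a0))) / beta
    else:
        t_exp = u / lam
        t_gomp = np.log1p(u * beta / (alpha * np.exp(beta * a0))) / beta
        lo = np.zeros(shape)
        hi = np.minimum(t_exp, t_gomp)

        def cumhaz(t):
            return lam * t + (alpha / beta) * np.exp(beta * a0) * np.expm1(beta * t)

        for _ in range(80):  # |hi-lo| shrinks below day resolution quickly
            mid = 0.5 * (lo + hi)
            too_low = cumhaz(mid) < u
            lo = np.where(too_low, mid, lo)
            hi = np.where(too_low, hi, mid)
        t = 0.5 * (lo + hi)
    out = a0 + t
    if np.ndim(birth_age) == 0 and np.ndim(rate_multiplier) == 0 and size is None:
        return float(out)
    return out


def gm_cumulative_hazard(age, hazard_params, rate_multiplier=1.0):
    """Cumulative Gompertz–Makeham hazard from birth,
    ``mult * (lambda*a + (alpha/beta)*(exp(beta*a) - 1))``."""
    lam, alpha, beta = hazard_params
    a = np.asarray(age, float)
    return rate_multiplier * (lam * a + (alpha / beta) * np.expm1(beta * a))


def gm_survival(age, hazard_params, rate_multiplier=1.0, from_age=0.0):
    """Survivor function S(age | alive at from_age) for the generator's
    hazard — the closed-form oracle for sampled death ages."""
    H = gm_cumulative_hazard(age, hazard_params, rate_multiplier)
    H0 = gm_cumulative_hazard(from_age, hazard_params, rate_multiplier)
    return np.exp(-(H - H0))


def gm_central_rates(ages, hazard_params, rate_multiplier=1.0,
                     n_grid: int = 64) -> np.ndarray:
    """True central death rate m_x over each single-year age interval,
    ``(S(x) - S(x+1)) / integral_x^{x+1} S``, by Simpson quadrature.

    This is the quantity the Poisson stratum model estimates, so it is the
    discretisation-matched truth for life-table checks.
    """
    from scipy.integrate import simpson

    ages = np.asarray(ages, float)
    out = np.empty(ages.size)
    for i, x in enumerate(ages):
        g = np.linspace(x, x + 1.0, n_grid + 1)
        s = gm_survival(g, hazard_params, rate_multiplier)
        out[i] = (s[0] - s[-1]) / simpson(s, x=g)
    return out


def gm_life_expectancy_total(at_age, hazard_params, rate_multiplier=1.0,
                             max_age: float = 130.0) -> float:
    """Total expected length of life given survival to ``at_age``
    (``at_age`` + remaining expectancy), by quadrature of the survivor
    function — the continuous-time truth behind the life-table pipeline."""
    from scipy.integrate import quad

    val, _ = quad(lambda a: float(gm_survival(a, hazard_params,
                                              rate_multiplier,
                                              from_age=at_age)),
                  at_age, max_age, limit=200)
    return float(at_age + val)


def _practice_frame(cfg: SimulationConfig, practice_id: int,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Generate one practice's patients (vectorised)."""
    n = cfg.persons_per_practice
    start = as_days(np.datetime64(cfg.study_start, "D"))
    end = as_days(np.datetime64(cfg.study_end, "D"))

    # practice-level data window: some practices meet quality criteria late,
    # some stop contributing early
    q_offset_days = int(rng.integers(0, int(16 * DAYS_PER_YEAR)))
    quality_start = start + np.timedelta64(q_offset_days, "D")
    if rng.random() < 0.8:
        last_collection = end
    else:
        span = int((end - quality_start).astype(int))
        last_collection = quality_start + np.timedelta64(
            int(rng.integers(span // 2, span + 1)), "D")

    sex = np.where(rng.random(n) < 0.5, "male", "female")
    # birth years 1910-2000: adults aged 18..100+ somewhere in the window
    birth_offset = rng.integers(0, int(91 * DAYS_PER_YEAR), size=n)
    birth = as_days(np.datetime64("1910-01-01")) + birth_offset.astype("timedelta64[D]")

    reg_age_days = rng.integers(30, int(40 * DAYS_PER_YEAR), size=n)
    registration = birth + reg_age_days.astype("timedelta64[D]")

    dereg = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    if cfg.deregistration_rate > 0:
        gap = rng.exponential(1.0 / cfg.deregistration_rate, size=n) * DAYS_PER_YEAR
        cand = registration + gap.astype(np.int64).astype("timedelta64[D]")
        keep = cand < last_collection
        dereg[keep] = cand[keep]

    exposed = rng.random(n) < cfg.exposure_prevalence
    has_id = exposed & (rng.random(n) < cfg.id_fraction)
    group = np.where(exposed, np.where(has_id, "exposed_with_id", "exposed_no_id"),
                     "comparison")

    # comorbidity onsets: group-specific prevalence, childhood onset so the
    # flag is established before any adult cohort entry
    como = {}
    hazard_mult = np.ones(n)
    for cond in CONDITIONS:
        prev = cfg.comorbidity_prevalences.get(cond, {})
        p = np.array([prev.get(g, 0.0) for g in group])
        has = rng.random(n) < p
        onset = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
        onset_age_days = rng.integers(int(1 * DAYS_PER_YEAR),
                                      int(18 * DAYS_PER_YEAR), size=n)
        onset[has] = birth[has] + onset_age_days[has].astype("timedelta64[D]")
        como[f"como_{cond}"] = onset
        hazard_mult = hazard_mult * np.where(
            has, cfg.comorbidity_hazard_ratios.get(cond, 1.0), 1.0)

    group_hr = np.array([cfg.group_hazard_ratios[g] for g in group])
    hazard_mult = hazard_mult * group_hr * np.where(
        sex == "male", cfg.sex_hazard_ratio, 1.0)

    # left truncation: only people alive at the later of registration and
    # the study start are ever present in the dataset, so death is drawn
    # conditional on survival to that age
    cond_days = np.maximum(reg_age_days, (start - birth).astype(np.int64))
    death_age = sample_death_age(
        cond_days / DAYS_PER_YEAR,
        (cfg.makeham_lambda, cfg.gompertz_alpha, cfg.gompertz_beta),
        hazard_mult, rng)
    death = birth + (death_age * DAYS_PER_YEAR).astype(np.int64).astype("timedelta64[D]")

    # exposure diagnosis: a candidate recording date is drawn uniformly over
    # the adult study window, independent of survival; the diagnosis is
    # recorded only if the person is still alive then.  Exposed-type people
    # who die first remain unrecorded (and so sit in the comparison pool),
    # emulating the underascertainment inherent in diagnosis registers.
    adult_from = np.maximum(birth + np.timedelta64(int(18 * DAYS_PER_YEAR), "D"),
                            start)
    window = (end - adult_from).astype(np.int64)
    offs = (rng.random(n) * (window + 1)).astype(np.int64)
    dx_cand = adult_from + offs.astype("timedelta64[D]")
    recorded = exposed & (dx_cand < death)
    has_id &= recorded
    dx = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    dx[recorded] = dx_cand[recorded]

    id_dx = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    delay = np.where(rng.random(n) < cfg.id_delay_fraction,
                     (rng.random(n) * 10 * DAYS_PER_YEAR).astype(np.int64), 0)
    id_dx[has_id] = dx[has_id] + delay[has_id].astype("timedelta64[D]")
    # keep the death date only while it can ever be observed; deaths after
    # the administrative end are simply unobserved (NaT keeps the CSV small)
    observable = death <= end
    death_out = np.where(observable, death, np.datetime64("NaT")).astype("datetime64[D]")
    certainty = np.where(
        observable,
        np.where(rng.random(n) < cfg.possible_death_fraction, "possible", "definite"),
        "")

    townsend = rng.integers(1, 6, size=n).astype(float)
    townsend[rng.random(n) < 0.2] = np.nan

    df = pd.DataFrame({
        "person_id": [f"p{practice_id:03d}-{i:05d}" for i in range(n)],
        "practice_id": practice_id,
        "sex": sex,
        "birth_date": birth,
        "registration_date": registration,
        "deregistration_date": dereg,
        "practice_quality_start": quality_start,
        "practice_last_collection": last_collection,
        "exposure_diagnosis_date": dx,
        "id_diagnosis_date": id_dx,
        **como,
        "death_date": death_out,
        "death_certainty": certainty,
        "townsend_quintile": townsend,
    })

    # scrub events recorded after death (the record ends at death)
    dd = df["death_date"].to_numpy("datetime64[D]")
    for col in ("deregistration_date", "exposure_diagnosis_date", "id_diagnosis_date",
                *como.keys()):
        v = df[col].to_numpy("datetime64[D]")
        after = ~pd.isna(v) & ~pd.isna(dd) & (v > dd)
        if after.any():
            v = v.copy()
            v[after] = np.datetime64("NaT")
            df[col] = v
    return df


def generate_population(config: SimulationConfig) -> pd.DataFrame:
    """Generate the full synthetic population as a patient table.

    One row per person, schema as in :func:`read_population_csv`.  Child RNG
    streams are spawned per practice from the root seed, so enlarging
    ``n_practices`` leaves earlier practices byte-identical.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    frames = []
    for practice_id, child in enumerate(root.spawn(config.n_practices)):
        frames.append(_practice_frame(config, practice_id,
                                      np.random.Generator(np.random.PCG64(child))))
    return pd.concat(frames, ignore_index=True)


_DATE_COLS = ("birth_date", "registration_date", "deregistration_date",
              "practice_quality_start", "practice_last_collection",
              "exposure_diagnosis_date", "id_diagnosis_date",
              *(f"como_{c}" for c in CONDITIONS), "death_date")


def write_population_csv(df: pd.DataFrame, path) -> None:
    """RFC 4180 CSV with ISO-8601 dates; empty string marks missing."""
    out = df.copy()
    for col in _DATE_COLS:
        out[col] = pd.Series(out[col]).astype("datetime64[s]").dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_population_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"death_certainty": str}, keep_default_na=False,
                     na_values=[""])
    for col in _DATE_COLS:
        df[col] = pd.to_datetime(df[col], format="%Y-%m-%d").to_numpy("datetime64[D]")
    df["death_certainty"] = df["death_certainty"].fillna("")
    return df
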