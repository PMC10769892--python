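"""Descriptive tables and end-to-end pipeline orchestration.

Produces participant-characteristics summaries (counts, death percentages,
median ages and follow-up with IQRs, covariate prevalences, entry-period
bands), age-banded mortality rates per 100,000 person-years with exact
Poisson (Garwood) confidence limits, and a fully reproducible
simulate → build → split → fit → life-table run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .cohort_builder import (COVARIATE_COLS, MatchedCohort, build_cohort,
                             write_intervals_csv)
from .dates import years_between
from .life_table import build_life_table, simulate_ci
from .persontime import aggregate_strata
from .rate_model import (fit_poisson_quadratic, predict_rates,
                         standardised_mortality_ratio, adjusted_rate_ratio)
from .synthetic_cohort import (SimulationConfig, generate_population,
                               write_population_csv)

__all__ = ["summarise_cohort", "banded_rate_table", "run_pipeline",
           "death_percentage"]

log = logging.getLogger("ehr_lifegap")

AGE_BANDS = ((18, 24), (25, 34), (35, 44), (45, 54), (55, 64), (65, 100))
ENTRY_PERIODS = ((1989, 1999), (2000, 2009), (2010, 2019))


def death_percentage(n_deaths: int, n_individuals: int) -> float:
    """Percentage of individuals who died, rounded half-up to 2 decimals —
    the display convention used in the participant tables."""
    if n_individuals == 0:
        raise ValueError("cannot compute a percentage of zero individuals")
    pct = Decimal(100 * n_deaths) / Decimal(n_individuals)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _median_iqr(x: np.ndarray):
    """Median and IQR by linear-interpolation quantiles (the numpy default),
    as recorded in the table metadata."""
    if len(x) == 0:
        return None
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}


def summarise_cohort(cohort: MatchedCohort) -> pd.DataFrame:
    """Participant characteristics per (cohort, group, sex).

    A person appearing in several intervals of the same (cohort, group) is
    counted once, at their earliest entry.  Empty groups simply do not
    appear; empty summary statistics are missing (None), never zero.
    """
    iv = cohort.intervals
    rows = []
    for (coh, group, sex), g in iv.groupby(["cohort", "group", "sex"],
                                           observed=True):
        # one row per person: earliest entry, latest exit, any death
        per = g.sort_values("entry_date").groupby("person_id", observed=True).agg(
            entry_date=("entry_date", "min"),
            exit_date=("exit_date", "max"),
            died=("died", "any"),
            birth_date=("birth_date", "first"),
            practice_id=("practice_id", "first"),
            **{c: (c, "first") for c in COVARIATE_COLS if c in g.columns},
        )
        n = len(per)
        deaths = int(per["died"].sum())
        entry_age = years_between(per["birth_date"], per["entry_date"])
        followup = years_between(per["entry_date"], per["exit_date"])
        death_age = years_between(per.loc[per["died"], "birth_date"],
                                  per.loc[per["died"], "exit_date"])
        entry_year = (per["entry_date"].to_numpy("datetime64[Y]")
                      .astype(np.int64) + 1970)
        row = {
            "cohort": coh, "group": group, "sex": sex,
            "n_individuals": n,
            "n_practices": int(per["practice_id"].nunique()),
            "n_deaths": deaths,
            "percent_deaths": death_percentage(deaths, n),
            "age_at_death": _median_iqr(np.asarray(death_age)),
            "age_at_entry": _median_iqr(np.asarray(entry_age)),
            "followup_years": _median_iqr(np.asarray(followup)),
        }
        for lo, hi in AGE_BANDS:
            top = np.inf if (lo, hi) == AGE_BANDS[-1] else hi + 1
            # year-of-birth matching lets a comparison enter a few months
            # short of 18; the bottom band is open below
            bottom = -np.inf if (lo, hi) == AGE_BANDS[0] else lo
            in_band = (entry_age >= bottom) & (entry_age < top)
            row[f"entry_{lo}_{'plus' if top is np.inf else hi}"] = int(in_band.sum())
        for lo, hi in ENTRY_PERIODS:
            row[f"period_{lo}_{hi}"] = int(((entry_year >= lo)
                                            & (entry_year <= hi)).sum())
        for c in COVARIATE_COLS:
            if c in per.columns:
                row[f"prev_{c[4:]}"] = float(per[c].mean())
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["quantile_method"] = "linear interpolation"
    return out


def _garwood_ci(k: int, alpha: float = 0.05):
    """Exact Poisson CI for a count via chi-square quantiles."""
    lo = 0.0 if k == 0 else stats.chi2.ppf(alpha / 2, 2 * k) / 2.0
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * (k + 1)) / 2.0
    return lo, hi


def banded_rate_table(strata: pd.DataFrame, per: float = 100_000.0,
                      bands=AGE_BANDS) -> pd.DataFrame:
    """Mortality rates per ``per`` person-years by age band, with exact
    Poisson (Garwood) confidence limits on the death count."""
    if len(strata) == 0:
        raise ValueError("strata table is empty")
    d = strata.copy()
    labels, edges = [], []
    for lo, hi in bands:
        top = hi if (lo, hi) != bands[-1] else int(d["age"].max())
        labels.append(f"{lo}-{hi}" if (lo, hi) != bands[-1] else f"{lo}+")
        edges.append((lo, top))
    def band_of(age):
        for lab, (lo, top) in zip(labels, edges):
            if lo <= age <= top:
                return lab
        return None
    d["band"] = d["age"].map(band_of)
    d = d.loc[d["band"].notna()]
    keys = [c for c in ("cohort", "group", "sex") if c in d.columns] + ["band"]
    agg = d.groupby(keys, as_index=False, observed=True)[
        ["deaths", "person_years"]].sum()
    rates, los, his = [], [], []
    for _, r in agg.iterrows():
        py = r["person_years"]
        k = int(r["deaths"])
        lo, hi = _garwood_ci(k)
        rates.append(k / py * per if py > 0 else np.nan)
        los.append(lo / py * per if py > 0 else np.nan)
        his.append(hi / py * per if py > 0 else np.nan)
    agg["rate"] = rates
    agg["ci_low"] = los
    agg["ci_high"] = his
    agg["band"] = pd.Categorical(agg["band"], categories=labels, ordered=True)
    return agg.sort_values(keys, ignore_index=True)


def _config_hash(cfg: SimulationConfig) -> str:
    blob = yaml.safe_dump(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: SimulationConfig, out_dir, *, n_sim: int = 10_000,
                 include_possible_deaths: bool = False,
                 population: pd.DataFrame | None = None) -> dict:
    """Run the whole analysis and persist every intermediate artifact.

    simulate → build cohorts → Lexis split → Poisson fits → SMRs →
    life tables → summary report.  Every output is a pure function of
    (config, seed): two runs with the same config produce byte-identical
    bundles.  ``population`` may be supplied to skip the simulation stage
    (external data with the same schema).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        if population is None:
            population = generate_population(config)
            write_population_csv(population, out / "population.csv")
        log.info("simulate: %d persons", len(population))

        stage = "build-cohort"
        cohort = build_cohort(population, k=config.comparison_ratio,
                              study_start=config.study_start,
                              study_end=config.study_end,
                              include_possible_deaths=include_possible_deaths,
                              seed=config.seed)
        write_intervals_csv(cohort, out / "intervals.csv")
        log.info("build-cohort: %d intervals, report=%s",
                 len(cohort.intervals), cohort.match_report)

        stage = "split"
        strata = aggregate_strata(cohort)
        strata.to_csv(out / "strata.csv", index=False)
        log.info("split: %d strata, %.1f person-years", len(strata),
                 strata["person_years"].sum())

        stage = "fit"
        ages = np.arange(18, 101)
        results: dict = {"provenance": {
            "seed": config.seed, "config_sha256": _config_hash(config),
            "version": __version__, "n_sim": n_sim,
            "include_possible_deaths": include_possible_deaths,
        }, "match_report": cohort.match_report, "cohorts": {}}
        fits = {}
        for coh in sorted(strata["cohort"].unique()):
            sub = strata.loc[strata["cohort"] == coh]
            exp_strata = sub.loc[sub["group"] != "comparison"]
            cmp_strata = sub.loc[sub["group"] == "comparison"]
            smr = standardised_mortality_ratio(exp_strata, cmp_strata)
            entry = {"smr": smr.to_dict(), "by_sex": {}}
            # covariate-adjusted model needs covariate-level strata
            cov_strata = aggregate_strata(
                cohort.intervals.loc[cohort.intervals["cohort"] == coh],
                extra_cols=COVARIATE_COLS)
            adj = adjusted_rate_ratio(cov_strata, covariates=COVARIATE_COLS)
            unadj = adjusted_rate_ratio(cov_strata, covariates=())
            entry["rate_ratio_unadjusted"] = unadj.to_dict()
            entry["rate_ratio_adjusted"] = adj.to_dict()
            for sex in ("male", "female"):
                e = exp_strata.loc[exp_strata["sex"] == sex]
                c = cmp_strata.loc[cmp_strata["sex"] == sex]
                fit_e = fit_poisson_quadratic(e, label=f"{coh} exposed {sex}")
                fit_c = fit_poisson_quadratic(c, label=f"{coh} comparison {sex}")
                fits[(coh, "exposed", sex)] = fit_e
                fits[(coh, "comparison", sex)] = fit_c
                stage = "lifetable"
                ci = simulate_ci(fit_e, fit_c, n_sim=n_sim, seed=config.seed)
                lt_e = build_life_table(predict_rates(fit_e, ages))
                lt_c = build_life_table(predict_rates(fit_c, ages))
                lt_e.table.to_csv(out / f"lifetable_{coh}_exposed_{sex}.csv",
                                  index=False)
                lt_c.table.to_csv(out / f"lifetable_{coh}_comparison_{sex}.csv",
                                  index=False)
                entry["by_sex"][sex] = {
                    "fit_exposed": fit_e.to_dict(),
                    "fit_comparison": fit_c.to_dict(),
                    "e18_exposed": ci["exposed"].to_dict(),
                    "e18_comparison": ci["comparison"].to_dict(),
                    "yll": ci["yll"].to_dict(),
                }
                stage = "fit"
            results["cohorts"][coh] = entry

        stage = "report"
        summary = summarise_cohort(cohort)
        summary.to_json(out / "summary.json", orient="records", indent=2)
        banded = banded_rate_table(strata)
        banded.to_csv(out / "banded_rates.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True)
        log.info("report: written to %s", out)
        return results
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
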