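"""Lexis expansion: follow-up time split by single year of attained age.

Each day of follow-up is assigned to the person's completed age on that day
(the birthday itself counts toward the new age).  Days before the 18th
birthday are dropped; ages above the cap are pooled into the open stratum
at the cap.  All splitting is exact calendar-day arithmetic — person-time
is converted to years (days / 365.25) only at aggregation.

A death is assigned to the completed age on the last day of follow-up
(exit date minus one day, intervals being half-open), which guarantees
every death lands in a stratum holding at least one day of person-time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dates import DAYS_PER_YEAR, ONE_DAY, add_years, as_days, completed_age
from .cohort_builder import MatchedCohort

__all__ = ["split_person_time", "aggregate_strata", "AGE_MIN", "AGE_MAX"]

AGE_MIN = 18
AGE_MAX = 100


def split_person_time(birth_date, entry_date, exit_date,
                      age_min: int = AGE_MIN, age_max: int = AGE_MAX):
    """Split one half-open interval [entry, exit) into (age, days) pieces.

    Returns a list of ``(age, days)`` with strictly positive day counts, in
    increasing age order.  Days lived below ``age_min`` are discarded; all
    days at ages above ``age_max`` are pooled into the ``age_max`` stratum.
    """
    birth = as_days(birth_date)
    entry = as_days(entry_date)
    exit_ = as_days(exit_date)
    if entry >= exit_:
        return []
    a_start = max(int(completed_age(birth, entry)), age_min)
    out = []
    for age in range(a_start, age_max):
        seg_start = max(entry, add_years(birth, age))
        seg_end = min(exit_, add_years(birth, age + 1))
        days = int((seg_end - seg_start).astype(int))
        if days > 0:
            out.append((age, days))
        if seg_end >= exit_:
            return out
    # open stratum: everything at and above age_max
    seg_start = max(entry, add_years(birth, age_max))
    days = int((exit_ - seg_start).astype(int))
    if days > 0:
        out.append((age_max, days))
    return out


def _age_days_matrix(birth, entry, exit_, age_min: int, age_max: int):
    """Vectorised day counts per age stratum for many intervals.

    Yields ``(age, days_array)`` for each age in [age_min, age_max]; loops
    over the ~83 ages, not over intervals.
    """
    for age in range(age_min, age_max):
        lo = np.maximum(entry, add_years(birth, age))
        hi = np.minimum(exit_, add_years(birth, age + 1))
        days = np.maximum((hi - lo).astype(np.int64), 0)
        yield age, days
    lo = np.maximum(entry, add_years(birth, age_max))
    days = np.maximum((exit_ - lo).astype(np.int64), 0)
    yield age_max, days


def aggregate_strata(cohort, age_min: int = AGE_MIN, age_max: int = AGE_MAX,
                     extra_cols=()) -> pd.DataFrame:
    """Aggregate deaths and person-years by (cohort, group, sex, age).

    Accepts a :class:`MatchedCohort` or its ``intervals`` frame.  With
    ``extra_cols`` (e.g. covariate flags) the strata are additionally split
    by those columns — the form needed for covariate-adjusted rate models.

    Returns a DataFrame with columns ``cohort, group, sex, [extra...], age,
    deaths, person_years`` containing every stratum with positive
    person-time or at least one death.
    """
    intervals = cohort.intervals if isinstance(cohort, MatchedCohort) else cohort
    key_cols = [c for c in ("cohort", "group", "sex") if c in intervals.columns]
    key_cols += list(extra_cols)
    if len(intervals) == 0:
        return pd.DataFrame(columns=[*key_cols, "age", "deaths", "person_years"])

    birth = intervals["birth_date"].to_numpy("datetime64[D]")
    entry = intervals["entry_date"].to_numpy("datetime64[D]")
    exit_ = intervals["exit_date"].to_numpy("datetime64[D]")
    died = intervals["died"].to_numpy(bool)

    keys = intervals[key_cols].copy()
    pieces = []
    for age, days in _age_days_matrix(birth, entry, exit_, age_min, age_max):
        nz = days > 0
        if not nz.any():
            continue
        part = keys.loc[nz].copy()
        part["age"] = age
        part["days"] = days[nz]
        pieces.append(part)
    long = pd.concat(pieces, ignore_index=True)
    py = (long.groupby([*key_cols, "age"], as_index=False, sort=True, observed=True)
          ["days"].sum())

    # deaths: completed age on the last day lived, clipped into the cap,
    # dropped if below age_min
    death_age = completed_age(birth, exit_ - ONE_DAY)
    death_age = np.minimum(death_age, age_max)
    keep = died & (death_age >= age_min)
    dk = keys.loc[keep].copy()
    dk["age"] = death_age[keep]
    deaths = (dk.groupby([*key_cols, "age"], as_index=False, sort=True,
                         observed=True).size().rename(columns={"size": "deaths"}))

    out = py.merge(deaths, on=[*key_cols, "age"], how="outer")
    out["days"] = out["days"].fillna(0).astype(np.int64)
    out["deaths"] = out["deaths"].fillna(0).astype(np.int64)
    out["person_years"] = out["days"] / DAYS_PER_YEAR
    out = out.drop(columns="days")
    return out.sort_values([*key_cols, "age"], ignore_index=True)
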