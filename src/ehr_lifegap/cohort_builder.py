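"""Eligibility, follow-up windows, and exposure density sampling.

Cohort entry for a diagnosed person is the latest of: the diagnosis date,
the practice's data-quality start, registration plus six months, and the
study start.  Exit is the earliest of death, deregistration, the practice's
last data collection, and the administrative study end.  Starting exposed
follow-up at diagnosis keeps immortal time out of the analysis.

Comparison participants are drawn by exposure density (risk-set) sampling:
for each diagnosed person entering the cohort, k people of the same sex,
birth year and practice who are under follow-up and undiagnosed at that
index date are sampled without replacement and assigned the same entry
date.  A comparison participant who is later diagnosed is censored at their
own diagnosis date and may re-enter as exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .dates import ONE_DAY, as_days
from .synthetic_cohort import CONDITIONS

__all__ = [
    "MatchedCohort",
    "compute_entry_date",
    "compute_exit_date",
    "exposure_density_match",
    "build_cohort",
    "write_intervals_csv",
    "read_intervals_csv",
]

COVARIATE_COLS = tuple(f"cov_{c}" for c in CONDITIONS)

_REQUIRED_COLS = (
    "person_id", "practice_id", "sex", "birth_date", "registration_date",
    "deregistration_date", "practice_quality_start", "practice_last_collection",
    "exposure_diagnosis_date", "id_diagnosis_date", "death_date", "death_certainty",
)

_NAT = np.datetime64("NaT")


@dataclass
class MatchedCohort:
    """Follow-up intervals for both exposure cohorts and their matched
    comparison groups.

    ``intervals`` has one row per follow-up segment with columns:
    person_id, practice_id, cohort ('no_id'/'with_id'), group
    ('exposed_no_id'/'exposed_with_id'/'comparison'), sex, birth_date,
    entry_date, exit_date, died, death_certainty, matched_set_id, and one
    ``cov_<condition>`` flag per comorbidity frozen at entry.
    """

    intervals: pd.DataFrame
    k: int
    match_report: dict = field(default_factory=dict)


def _half_year_later(dates) -> np.ndarray:
    """Date + 6 calendar months (vectorised)."""
    s = pd.Series(pd.to_datetime(as_days(np.atleast_1d(dates))))
    return (s + pd.DateOffset(months=6)).to_numpy().astype("datetime64[D]")


def _nanmin_dates(*arrays) -> np.ndarray:
    """Element-wise earliest date, ignoring NaT."""
    out = arrays[0].copy()
    for a in arrays[1:]:
        take = ~pd.isna(a) & (pd.isna(out) | (a < out))
        out[take] = a[take]
    return out


def compute_entry_date(patient, study_start):
    """Latest of diagnosis, practice quality start, registration + 6 months,
    and study start; ``None`` for a person who was never diagnosed or whose
    entry would fall at/after their exit bound (degenerate records never
    enter; a definite death on the entry day is kept as a one-day interval
    by the cohort builder)."""
    dx = patient["exposure_diagnosis_date"]
    if pd.isna(dx):
        return None
    entry = max(
        as_days(dx),
        as_days(patient["practice_quality_start"]),
        _half_year_later(patient["registration_date"])[0],
        as_days(np.datetime64(study_start, "D")),
    )
    bounds = [as_days(patient["_study_end"])] if "_study_end" in patient else []
    death_day = None
    for col in ("death_date", "deregistration_date", "practice_last_collection"):
        v = patient.get(col)
        if v is not None and not pd.isna(v):
            bounds.append(as_days(v))
            if col == "death_date":
                death_day = as_days(v)
    exit_bound = min(bounds) if bounds else None
    if exit_bound is not None and entry >= exit_bound:
        if not (death_day is not None and entry == exit_bound == death_day):
            return None
    return entry


def compute_exit_date(patient, study_end, include_possible_deaths=False):
    """Earliest of death, deregistration, last practice collection and the
    administrative end; the death flag is only set when that earliest date
    is a death and the death is definite (or possible deaths are included)."""
    end = as_days(np.datetime64(study_end, "D"))
    exit_date = end
    for col in ("deregistration_date", "practice_last_collection", "death_date"):
        v = patient.get(col)
        if v is not None and not pd.isna(v):
            exit_date = min(exit_date, as_days(v))
    died = False
    dd = patient.get("death_date")
    if dd is not None and not pd.isna(dd) and as_days(dd) == exit_date:
        certainty = patient.get("death_certainty", "definite")
        died = certainty == "definite" or bool(include_possible_deaths)
    return exit_date, died


class _MatchPool:
    """Pool of potential comparison participants indexed by
    (practice, sex, birth year) with vectorised eligibility checks."""

    def __init__(self, population: pd.DataFrame):
        pop = population
        birth = pop["birth_date"].to_numpy("datetime64[D]")
        birth_year = birth.astype("datetime64[Y]").astype(np.int64) + 1970
        self.reg6 = _half_year_later(pop["registration_date"])
        self.quality = pop["practice_quality_start"].to_numpy("datetime64[D]")
        self.dereg = pop["deregistration_date"].to_numpy("datetime64[D]")
        self.death = pop["death_date"].to_numpy("datetime64[D]")
        self.dx = pop["exposure_diagnosis_date"].to_numpy("datetime64[D]")
        self.id_dx = pop["id_diagnosis_date"].to_numpy("datetime64[D]")
        keys = pd.DataFrame({
            "practice": pop["practice_id"].to_numpy(),
            "sex": pop["sex"].to_numpy(),
            "byear": birth_year,
        })
        self._groups = {k: idx.to_numpy() for k, idx in
                        keys.groupby(["practice", "sex", "byear"]).groups.items()}

    def eligible(self, practice, sex, birth_year, index_date) -> np.ndarray:
        """Positional indices of pool members eligible at the index date."""
        idx = self._groups.get((practice, sex, birth_year))
        if idx is None:
            return np.empty(0, dtype=np.int64)
        t = as_days(index_date)
        ok = (self.reg6[idx] <= t) & (self.quality[idx] <= t)
        for arr in (self.dereg, self.death, self.dx, self.id_dx):
            v = arr[idx]
            ok &= pd.isna(v) | (v > t)
        return idx[ok]


def exposure_density_match(exposed, pool, k, rng, index_date=None) -> np.ndarray:
    """Sample up to ``k`` comparison participants for one exposed person.

    ``pool`` may be a population DataFrame or a prebuilt :class:`_MatchPool`.
    Candidates must share sex, birth year and practice, be registered and
    past their six-month run-in, still under observation, and have neither
    an exposure nor an intellectual-disability diagnosis on or before the
    index date.  Returns sorted positional indices into the pool population;
    if fewer than ``k`` are eligible, all of them are returned.
    """
    if not isinstance(pool, _MatchPool):
        pool = _MatchPool(pool)
    if index_date is None:
        index_date = exposed["entry_date"]
    birth_year = int(as_days(exposed["birth_date"]).astype("datetime64[Y]")
                     .astype(np.int64)) + 1970
    cand = pool.eligible(exposed["practice_id"], exposed["sex"], birth_year,
                         index_date)
    if "_pos" in exposed:  # never match a person to themselves
        cand = cand[cand != exposed["_pos"]]
    if len(cand) <= k:
        return np.sort(cand)
    return np.sort(rng.choice(cand, size=k, replace=False))


def _validate_population(pop: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED_COLS if c not in pop.columns]
    if missing:
        raise ValueError(f"population table missing columns: {missing}")
    birth = pop["birth_date"].to_numpy("datetime64[D]")
    reg = pop["registration_date"].to_numpy("datetime64[D]")
    bad = pop.loc[~(birth < reg), "person_id"]
    if len(bad):
        raise ValueError(
            "birth_date must precede registration_date; offending person_ids: "
            f"{bad.head().tolist()}")
    death = pop["death_date"].to_numpy("datetime64[D]")
    has_death = ~pd.isna(death)
    bad = pop.loc[has_death & (death < reg), "person_id"]
    if len(bad):
        raise ValueError(
            f"death_date precedes registration_date for person_ids: "
            f"{bad.head().tolist()}")
    cert = pop["death_certainty"].fillna("").to_numpy()
    bad = pop.loc[has_death != np.isin(cert, ["definite", "possible"]), "person_id"]
    if len(bad):
        raise ValueError(
            "death_certainty must be set iff death_date is present; person_ids: "
            f"{bad.head().tolist()}")


def build_cohort(population: pd.DataFrame, *, k: int = 10,
                 study_start=date(1989, 1, 1), study_end=date(2019, 1, 16),
                 include_possible_deaths: bool = False,
                 seed: int = 0) -> MatchedCohort:
    """Build both exposure cohorts and their matched comparison groups.

    A person whose intellectual-disability (ID) record begins after their
    exposure diagnosis contributes to the no-ID cohort from entry until the
    ID date (censored there), and to the with-ID cohort from the ID date
    onward; each segment is matched at its own start date.  Comorbidity
    covariates are frozen at each interval's entry date.

    The sensitivity toggle ``include_possible_deaths`` changes event flags
    only: entry/exit dates (and hence person-time) are identical either way,
    except for the one-day interval granted to a death on the entry day.
    """
    _validate_population(population)
    pop = population.reset_index(drop=True)
    n = len(pop)
    end = np.full(n, np.datetime64(study_end, "D"), dtype="datetime64[D]")
    pool = _MatchPool(pop)
    rng = np.random.default_rng(seed)

    person_id = pop["person_id"].to_numpy()
    practice = pop["practice_id"].to_numpy()
    sex = pop["sex"].to_numpy()
    birth = pop["birth_date"].to_numpy("datetime64[D]")
    birth_year = birth.astype("datetime64[Y]").astype(np.int64) + 1970
    death = pop["death_date"].to_numpy("datetime64[D]")
    certainty = pop["death_certainty"].fillna("").to_numpy()
    dx = pop["exposure_diagnosis_date"].to_numpy("datetime64[D]")
    id_dx = pop["id_diagnosis_date"].to_numpy("datetime64[D]")

    # vectorised exit dates and event flags for every person
    exit_all = _nanmin_dates(end, pool.dereg,
                             pop["practice_last_collection"].to_numpy("datetime64[D]"))
    exit_all = _nanmin_dates(exit_all, death)
    is_death = ~pd.isna(death) & (death == exit_all)
    died_all = is_death & ((certainty == "definite") | include_possible_deaths)

    # comparison follow-up additionally censored at own (later) diagnosis
    own_dx = _nanmin_dates(dx.copy(), id_dx)
    comp_exit = exit_all.copy()
    comp_died = died_all.copy()
    cens = ~pd.isna(own_dx) & (own_dx < comp_exit)
    comp_exit[cens] = own_dx[cens]
    comp_died[cens] = False

    onset = {c: (pop[f"como_{c}"].to_numpy("datetime64[D]")
                 if f"como_{c}" in pop else np.full(n, _NAT, dtype="datetime64[D]"))
             for c in CONDITIONS}

    # entry dates for diagnosed persons
    entry_all = np.maximum.reduce([
        dx, pool.quality, pool.reg6,
        np.full(n, np.datetime64(study_start, "D"), dtype="datetime64[D]"),
    ])

    rows: list[tuple] = []
    report = {"n_exposed": 0, "n_exposed_intervals": 0, "full_sets": 0,
              "partial_sets": 0, "total_shortfall": 0, "ineligible_exposed": 0}

    def emit(pos: int, cohort: str, group: str, entry, exit_date, died_flag,
             msid: int) -> None:
        # death on the entry day: one-day interval (regardless of whether the
        # death is counted as an event, so the possible-deaths toggle changes
        # event flags only, never person-time)
        if is_death[pos] and exit_date == entry == death[pos]:
            exit_date = exit_date + ONE_DAY
        if exit_date <= entry:
            return  # zero-length follow-up dropped
        covs = tuple(int(not pd.isna(onset[c][pos]) and onset[c][pos] <= entry)
                     for c in CONDITIONS)
        rows.append((person_id[pos], practice[pos], cohort, group, sex[pos],
                     birth[pos], entry, exit_date, bool(died_flag),
                     certainty[pos] if died_flag else "", msid) + covs)

    set_id = 0
    for pos in np.flatnonzero(~pd.isna(dx)):
        report["n_exposed"] += 1
        entry = entry_all[pos]
        exit_date = exit_all[pos]
        if entry > exit_date or (entry == exit_date and not is_death[pos]):
            report["ineligible_exposed"] += 1
            continue
        died_flag = died_all[pos]
        idd = id_dx[pos]

        segments: list[tuple] = []  # (cohort, group, entry, exit, died)
        if pd.isna(idd) or idd >= exit_date:
            segments.append(("no_id", "exposed_no_id", entry, exit_date, died_flag))
        elif idd <= entry:
            segments.append(("with_id", "exposed_with_id", entry, exit_date,
                             died_flag))
        else:
            segments.append(("no_id", "exposed_no_id", entry, idd, False))
            segments.append(("with_id", "exposed_with_id", idd, exit_date,
                             died_flag))

        for cohort, group, seg_entry, seg_exit, seg_died in segments:
            msid = set_id
            set_id += 1
            report["n_exposed_intervals"] += 1
            emit(pos, cohort, group, seg_entry, seg_exit, seg_died, msid)

            cand = pool.eligible(practice[pos], sex[pos], birth_year[pos],
                                 seg_entry)
            cand = cand[cand != pos]
            if len(cand) <= k:
                chosen = np.sort(cand)
            else:
                chosen = np.sort(rng.choice(cand, size=k, replace=False))
            if len(chosen) == k:
                report["full_sets"] += 1
            else:
                report["partial_sets"] += 1
                report["total_shortfall"] += k - len(chosen)
            for cpos in chosen:
                emit(int(cpos), cohort, "comparison", seg_entry, comp_exit[cpos],
                     comp_died[cpos], msid)

    cols = ["person_id", "practice_id", "cohort", "group", "sex", "birth_date",
            "entry_date", "exit_date", "died", "death_certainty",
            "matched_set_id", *COVARIATE_COLS]
    intervals = pd.DataFrame(rows, columns=cols)
    if len(intervals):
        for col in ("birth_date", "entry_date", "exit_date"):
            intervals[col] = intervals[col].to_numpy("datetime64[D]")
    return MatchedCohort(intervals=intervals, k=k, match_report=report)


def write_intervals_csv(cohort: MatchedCohort, path) -> None:
    out = cohort.intervals.copy()
    for col in ("birth_date", "entry_date", "exit_date"):
        out[col] = pd.Series(out[col]).astype("datetime64[s]").dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_intervals_csv(path, k: int = 10) -> MatchedCohort:
    df = pd.read_csv(path, keep_default_na=False,
                     na_values=[""], dtype={"death_certainty": str})
    for col in ("birth_date", "entry_date", "exit_date"):
        df[col] = pd.to_datetime(df[col], format="%Y-%m-%d").to_numpy("datetime64[D]")
    df["death_certainty"] = df["death_certainty"].fillna("")
    df["died"] = df["died"].astype(bool)
    return MatchedCohort(intervals=df, k=k, match_report={})
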