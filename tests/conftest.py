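"""Shared fixtures: one small synthetic population and its derived
artifacts, built once per session so the unit suites stay fast."""

import numpy as np
import pandas as pd
import pytest

from ehr_lifegap import aggregate_strata, build_cohort
from ehr_lifegap.synthetic_cohort import (CONDITIONS, SimulationConfig,
                                          generate_population)

HAZARD = ("makeham_lambda", "gompertz_alpha", "gompertz_beta")


def small_config(seed=123, **overrides) -> SimulationConfig:
    base = dict(n_practices=4, persons_per_practice=2500,
                exposure_prevalence=0.05, seed=seed)
    base.update(overrides)
    return SimulationConfig(**base)


def neutral_comorbidities():
    """Comorbidity hazard ratios of 1 — marginal group rate ratios then
    equal the configured group hazard ratios exactly."""
    return {c: 1.0 for c in CONDITIONS}


@pytest.fixture(scope="session")
def config():
    return small_config()


@pytest.fixture(scope="session")
def population(config):
    return generate_population(config)


@pytest.fixture(scope="session")
def cohort(population):
    return build_cohort(population, k=10, seed=5)


@pytest.fixture(scope="session")
def strata(cohort):
    return aggregate_strata(cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def tiny_population() -> pd.DataFrame:
    """A hand-written two-practice population exercising every record
    feature: diagnosed/undiagnosed, late ID, possible death, deregistration."""
    def d(s):
        return np.datetime64(s, "D") if s else np.datetime64("NaT")

    cols = ["person_id", "practice_id", "sex", "birth_date",
            "registration_date", "deregistration_date",
            "practice_quality_start", "practice_last_collection",
            "exposure_diagnosis_date", "id_diagnosis_date",
            "death_date", "death_certainty", "townsend_quintile"]
    rows = [
        # exposed, dies (definite) during follow-up
        ("a1", 1, "male", "1960-05-10", "1980-01-01", None,
         "1990-01-01", "2019-01-16", "2000-06-01", None,
         "2010-03-15", "definite", 2),
        # exposed with later ID record: splits into two segments
        ("a2", 1, "male", "1960-04-02", "1979-06-01", None,
         "1990-01-01", "2019-01-16", "1998-02-01", "2005-08-01",
         None, "", 3),
        # exposed, possible death
        ("a3", 1, "female", "1970-01-20", "1990-01-01", None,
         "1990-01-01", "2019-01-16", "2001-01-01", None,
         "2008-07-07", "possible", 1),
        # comparison pool, same practice / sex / birth years
        *[(f"c{i}", 1, "male", f"1960-0{1 + i % 9}-15", "1978-01-01", None,
           "1990-01-01", "2019-01-16", None, None, None, "", 4)
          for i in range(12)],
        *[(f"f{i}", 1, "female", "1970-03-03", "1990-06-01", None,
           "1990-01-01", "2019-01-16", None, None, None, "", 5)
          for i in range(4)],
        # a comparison candidate later diagnosed themselves
        ("cx", 1, "male", "1960-07-07", "1978-01-01", None,
         "1990-01-01", "2019-01-16", "2012-05-05", None, None, "", 1),
        # deregisters early
        ("cd", 1, "male", "1960-08-08", "1978-01-01", "1995-01-01",
         "1990-01-01", "2019-01-16", None, None, None, "", 2),
        # other practice: never eligible for practice-1 sets
        ("z1", 2, "male", "1960-05-10", "1980-01-01", None,
         "1990-01-01", "2019-01-16", None, None, None, "", 3),
    ]
    df = pd.DataFrame(rows, columns=cols)
    for c in ("birth_date", "registration_date", "deregistration_date",
              "practice_quality_start", "practice_last_collection",
              "exposure_diagnosis_date", "id_diagnosis_date", "death_date"):
        df[c] = df[c].map(d).to_numpy("datetime64[D]")
    for cond in CONDITIONS:
        df[f"como_{cond}"] = np.full(len(df), np.datetime64("NaT"),
                                     dtype="datetime64[D]")
    # a1 has epilepsy from childhood (covariate set at entry)
    df.loc[df.person_id == "a1", "como_epilepsy"] = np.datetime64("1970-01-01")
    return df


@pytest.fixture()
def tiny_pop():
    return tiny_population()
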