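"""Calendar arithmetic on integer-day dates.

All follow-up arithmetic in this package is exact in days; conversion to
years (days / 365.25) happens only when person-time is aggregated.  Dates
are numpy ``datetime64[D]`` arrays throughout, so vectorised operations on
whole cohorts stay cheap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25

ONE_DAY = np.timedelta64(1, "D")


def as_days(dates) -> np.ndarray:
    """Coerce scalar/array/Series of dates to ``datetime64[D]``."""
    if isinstance(dates, pd.Series):
        dates = dates.to_numpy()
    return np.asarray(dates, dtype="datetime64[D]")


def add_years(dates, n_years) -> np.ndarray:
    """Anniversary of `dates` after `n_years` calendar years.

    A 29 February anniversary falls on 1 March in non-leap years (the
    convention used for birthdays in most administrative data).  Fully
    vectorised; `n_years` may be scalar or an array broadcastable to
    `dates`.
    """
    d = as_days(dates)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    n = np.broadcast_to(np.asarray(n_years, dtype=np.int64), d.shape)

    years = d.astype("datetime64[Y]")
    # day-of-year offset within the original year
    doy = (d - years.astype("datetime64[D]")).astype(np.int64)
    tgt_year = years + n.astype("timedelta64[Y]")
    month = ((d.astype("datetime64[M]") - years.astype("datetime64[M]"))
             .astype(np.int64))  # 0-based month
    day = (d - d.astype("datetime64[M]").astype("datetime64[D]")).astype(np.int64)

    # rebuild target date from (year, month, day); clamp 29 Feb -> 1 Mar
    tgt_month = tgt_year.astype("datetime64[M]") + month.astype("timedelta64[M]")
    candidate = tgt_month.astype("datetime64[D]") + day.astype("timedelta64[D]")
    # if day overflowed the month (only possible for 29 Feb), candidate is 1 Mar
    overflowed = (candidate.astype("datetime64[M]") != tgt_month)
    out = np.where(overflowed,
                   (tgt_month + 1).astype("datetime64[D]"),
                   candidate)
    # np.where drops the dtype to datetime64 generic; restore [D]
    out = out.astype("datetime64[D]")
    if scalar:
        return out[0]
    return out


def completed_age(birth_dates, on_dates) -> np.ndarray:
    """Completed age in whole years on a given day (birthday counts as the
    new age)."""
    b = np.atleast_1d(as_days(birth_dates))
    o = np.atleast_1d(as_days(on_dates))
    b, o = np.broadcast_arrays(b, o)
    by = b.astype("datetime64[Y]").astype(np.int64)
    oy = o.astype("datetime64[Y]").astype(np.int64)
    age = oy - by
    # subtract one if this year's birthday is still ahead
    bday = add_years(b, age)
    age = age - (bday > o).astype(np.int64)
    if np.isscalar(birth_dates) or (np.ndim(birth_dates) == 0 and np.ndim(on_dates) == 0):
        return int(age[0])
    return age


def years_between(start, end) -> np.ndarray:
    """Elapsed time in years (days / 365.25)."""
    delta = (as_days(end) - as_days(start)).astype(np.int64)
    return delta / DAYS_PER_YEAR
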