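"""Time strata and patient strata for the time-stratified case-crossover design.

Referent selection is time-stratified: all days sharing a case day's
(year, month, day-of-week) form one stratum, so each stratum holds 4 or 5
dates and trend, season and weekday are controlled by design.  Patients are
additionally stratified 18 ways by sex, age band and season.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import pandas as pd


class TimeStratumKey(NamedTuple):
    """Calendar cluster 'year : month : day of week' (ISO weekday, Mon=1)."""

    year: int
    month: int
    day_of_week: int


def build_time_strata(dates) -> pd.Series:
    """Map each date to its (year, month, ISO weekday) stratum key.

    Returns a Series of TimeStratumKey indexed by date.  The mapping is
    total: every date belongs to exactly one stratum, and dates sharing
    (year, month, weekday) share a key.
    """
    idx = pd.DatetimeIndex(dates)
    keys = [
        TimeStratumKey(int(y), int(m), int(w) + 1)
        for y, m, w in zip(idx.year, idx.month, idx.weekday)
    ]
    return pd.Series(keys, index=idx)


def assign_season(date) -> str:
    """Warm season is April-September; cold is October-March."""
    month = pd.Timestamp(date).month
    return "warm" if 4 <= month <= 9 else "cold"


# Age bands: 0-10, 11-60, 61+.  The upper band is labelled "Age 60+" for
# continuity with conventional reporting, but the cut sits at 61 by default
# (configurable via the `elderly_start` argument of age_band()).
AGE_BANDS = ("0-10", "11-60", "61+")
SEXES = ("female", "male")


def age_band(age: int, *, elderly_start: int = 61) -> str:
    if age < 0:
        raise ValueError("age must be non-negative")
    if age <= 10:
        return "0-10"
    if age < elderly_start:
        return "11-60"
    return "61+"


@dataclass(frozen=True)
class PatientStratum:
    """One of the 18 analysis subgroups (sex x age x season filters).

    Age and season filters are never simultaneously non-'all': the design
    crosses season with sex and age with sex, but not age with season.
    """

    label: str
    sex_filter: str = "all"      # all | female | male
    age_filter: str = "all"      # all | 0-10 | 11-60 | 61+
    season_filter: str = "all"   # all | warm | cold

    def __post_init__(self):
        if self.age_filter != "all" and self.season_filter != "all":
            raise ValueError("age and season filters cannot both be set")


def enumerate_patient_strata() -> list[PatientStratum]:
    """The 18 patient strata in canonical reporting order.

    3 sex-only strata, then 6 season-by-sex, then 9 age-by-sex.
    """
    strata = [
        PatientStratum("All"),
        PatientStratum("Female", sex_filter="female"),
        PatientStratum("Male", sex_filter="male"),
    ]
    for season in ("warm", "cold"):
        for sex, tag in (("all", "all"), ("female", "female"), ("male", "male")):
            strata.append(PatientStratum(
                f"{season.capitalize()} {tag}", sex_filter=sex,
                season_filter=season))
    for band, label in (("0-10", "Age 0-10"), ("11-60", "Age 11-60"),
                        ("61+", "Age 60+")):
        for sex, tag in (("all", "all"), ("female", "female"), ("male", "male")):
            strata.append(PatientStratum(
                f"{label} {tag}", sex_filter=sex, age_filter=band))
    assert len(strata) == 18
    return strata


def strata_to_csv(path) -> None:
    """Export the stratum definitions (label, sex, age, season) as CSV."""
    rows = [
        {"label": s.label, "sex": s.sex_filter, "age": s.age_filter,
         "season": s.season_filter}
        for s in enumerate_patient_strata()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
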