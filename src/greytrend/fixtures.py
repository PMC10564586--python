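"""Packaged national-surveillance summary tables.

Five survey waves (2000, 2005, 2010, 2014, 2020) of mean height, weight,
chest circumference and BMI for boys and girls aged 3-6, plus pooled
overweight/obesity detection rates observed at the first four waves, and the
published model-table cells used for cell-by-cell comparison.  Standard
deviations are carried as metadata only; modeling uses the means.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

from .series import Indicator, ObservationSeries, Sex

__all__ = [
    "load_means",
    "load_prevalence",
    "load_printed_model_tables",
    "load_printed_prevalence_table",
    "anthropometry_series",
    "prevalence_series",
    "ANTHROPOMETRY_INDICATORS",
]

ANTHROPOMETRY_INDICATORS = (
    Indicator.HEIGHT, Indicator.WEIGHT, Indicator.CHEST_CIRCUMFERENCE, Indicator.BMI,
)

#: Known misprints in the published tables, keyed by (indicator, sex, age, row).
ERRATA = {
    ("weight", "girls", 5, "b"): "printed b = 14.8 is inconsistent with the fitted column (~17.9)",
    ("weight", "girls", 6, "y2015"): "printed 22.5 is non-monotone against 2010 (20.9) and 2020 (22.1)",
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("greytrend.data").joinpath(name).open("r") as f:
        return pd.read_csv(f)


@lru_cache(maxsize=None)
def load_means() -> pd.DataFrame:
    """Mean +/- SD table: indicator, sex, age, year, mean, sd."""
    return _read("cnpfs_means.csv")


@lru_cache(maxsize=None)
def load_prevalence() -> pd.DataFrame:
    """Observed overweight/obesity detection rates (%): indicator, sex, year, value."""
    return _read("prevalence_rates.csv")


@lru_cache(maxsize=None)
def load_printed_model_tables() -> pd.DataFrame:
    """Published per-series model cells: indicator, sex, age, row, value.

    Rows: a1000 (10^3 a), b, fit_err_pct, y2000..y2030 fitted/predicted values,
    d*/p* growth deltas and percent changes.
    """
    return _read("printed_model_tables.csv")


@lru_cache(maxsize=None)
def load_printed_prevalence_table() -> pd.DataFrame:
    """Published prevalence forecasts: indicator, sex, row, value."""
    return _read("printed_prevalence_table.csv")


def anthropometry_series(indicator: Indicator | str, sex: Sex | str,
                         age_years: int) -> ObservationSeries:
    """The 5-wave mean series for one indicator/sex/age cell."""
    indicator, sex = Indicator(indicator), Sex(sex)
    df = load_means()
    sub = df[(df.indicator == indicator.value) & (df.sex == sex.value)
             & (df.age == age_years)].sort_values("year")
    if sub.empty:
        raise KeyError(f"no packaged series for {indicator.value}/{sex.value}/age {age_years}")
    return ObservationSeries(indicator=indicator, sex=sex, age_years=age_years,
                             points=tuple(zip(sub.year.astype(int), sub["mean"].astype(float))))


def prevalence_series(indicator: Indicator | str, sex: Sex | str) -> ObservationSeries:
    """The 4-wave detection-rate series for one rate/sex cell."""
    indicator, sex = Indicator(indicator), Sex(sex)
    df = load_prevalence()
    sub = df[(df.indicator == indicator.value) & (df.sex == sex.value)].sort_values("year")
    if sub.empty:
        raise KeyError(f"no packaged rate series for {indicator.value}/{sex.value}")
    return ObservationSeries(indicator=indicator, sex=sex, age_years=None,
                             points=tuple(zip(sub.year.astype(int), sub.value.astype(float))))
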