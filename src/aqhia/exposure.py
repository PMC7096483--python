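"""Annual exposure aggregation from daily monitoring-station records.

District and city annual means follow the station-mean convention: a
district's annual mean is the unweighted mean of its stations' annual means,
and the CITY mean is the unweighted mean over *all* stations. Districts with
no station in a given year are imputed with the CITY mean and flagged.
"""

from __future__ import annotations

import calendar
import warnings
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CITY",
    "POLLUTANTS",
    "station_annual_mean",
    "district_annual_exposure",
    "annual_exposure_table",
    "percent_change",
]

CITY = "CITY"
POLLUTANTS = ("PM2.5", "PM10", "SO2", "NO2", "CO", "O3")

#: fraction of the year below which a station-year triggers a coverage warning
COVERAGE_WARN = 0.75


def _days_in_year(year: int) -> int:
    return 366 if calendar.isleap(year) else 365


def station_annual_mean(records: pd.DataFrame, year: int) -> pd.DataFrame:
    """Per-station annual mean and coverage for one civil year.

    Parameters
    ----------
    records
        Long table with columns ``station_id, district_id, date, pollutant,
        value``; ``date`` parseable to datetime.
    year
        Civil year to aggregate (leap days count in the coverage denominator).

    Returns
    -------
    DataFrame with columns ``station_id, district_id, pollutant, mean,
    coverage``. Station-years with no records are simply absent (a warning
    is emitted naming them is not possible — absence is logged by caller).
    """
    if records.empty:
        raise ValueError(f"no records supplied for year {year}")
    dates = pd.to_datetime(records["date"])
    sub = records.loc[dates.dt.year == year]
    if sub.empty:
        raise ValueError(f"no records found for year {year}")
    if (sub["value"] < 0).any():
        raise ValueError("negative concentration values in station records")

    grouped = sub.groupby(["station_id", "district_id", "pollutant"], sort=True)
    out = grouped["value"].agg(mean="mean", n_days="count").reset_index()
    out["coverage"] = out["n_days"] / _days_in_year(year)
    low = out.loc[out["coverage"] < COVERAGE_WARN]
    for row in low.itertuples(index=False):
        warnings.warn(
            f"station {row.station_id} {row.pollutant} {year}: coverage "
            f"{row.coverage:.2f} below {COVERAGE_WARN}",
            stacklevel=2,
        )
    return out.drop(columns="n_days")


def district_annual_exposure(
    station_means: pd.DataFrame,
    station_to_district: Mapping[str, str],
    year: int,
    all_districts: Iterable[str] | None = None,
) -> pd.DataFrame:
    """District and CITY annual mean exposures from per-station annual means.

    District mean = unweighted mean over its stations; CITY mean = unweighted
    mean over all stations. Districts listed in ``all_districts`` but with no
    station that year receive the CITY mean with ``imputed = True``.

    Raises
    ------
    KeyError
        If a station id is not present in ``station_to_district``.
    """
    unmapped = sorted(set(station_means["station_id"]) - set(station_to_district))
    if unmapped:
        raise KeyError(f"stations not mapped to a district: {', '.join(unmapped)}")

    sm = station_means.copy()
    sm["district_id"] = sm["station_id"].map(station_to_district)

    rows = []
    for pollutant, part in sm.groupby("pollutant", sort=True):
        city_mean = float(part["mean"].mean())
        per_district = part.groupby("district_id")["mean"].agg(["mean", "count"])
        for district, stats in per_district.iterrows():
            rows.append((district, year, pollutant, float(stats["mean"]),
                         int(stats["count"]), False))
        covered = set(per_district.index)
        for district in sorted(set(all_districts or []) - covered):
            rows.append((district, year, pollutant, city_mean, 0, True))
        rows.append((CITY, year, pollutant, city_mean, int(len(part)), False))
    return pd.DataFrame(
        rows, columns=["unit_id", "year", "pollutant", "mean", "n_station_years", "imputed"]
    )


def annual_exposure_table(
    records: pd.DataFrame,
    station_to_district: Mapping[str, str],
    years: Iterable[int],
    all_districts: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Aggregate daily records to annual exposures for several years."""
    parts = []
    for year in years:
        means = station_annual_mean(records, year)
        parts.append(
            district_annual_exposure(means, station_to_district, year, all_districts)
        )
    return pd.concat(parts, ignore_index=True)


def percent_change(mean_ref: float, mean_new: float) -> float:
    """Percent change from a reference year; positive values are reductions."""
    if mean_ref <= 0:
        raise ValueError(f"reference mean must be > 0, got {mean_ref}")
    return 100.0 * (mean_ref - mean_new) / mean_ref
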