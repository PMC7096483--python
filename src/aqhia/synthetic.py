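"""Seeded generators for every pipeline input, plus the published-tables fixture.

The generators emulate the surveillance and monitoring data of a large,
heavily polluted northern-Chinese city over 2013-2017:

* a monitoring network that grows from 15 to 32 stations in 2016, with four
  outlying districts unmonitored before the expansion;
* daily pollutant series with winter peaks (PM2.5, PM10, SO2, NO2, CO) or a
  summer peak (O3), multiplicative lognormal noise, and annual city means
  that decline (or, for O3, rise) year over year;
* ~0.7 M-person districts whose total grows linearly from 7.0 M to 7.3 M;
* plausible cause-specific baseline mortality/morbidity rates;
* unit costs spanning large mortality (willingness-to-pay) and small
  morbidity (cost-of-illness) endpoints, and default concentration-response
  parameters.

All randomness flows from a single master seed through independent
per-generator streams, so identical (seed, config) pairs yield byte-identical
output files.
"""

from __future__ import annotations

import calendar
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .exposure import POLLUTANTS

__all__ = [
    "SimulationConfig",
    "MORTALITY_ENDPOINTS",
    "MORBIDITY_ENDPOINTS",
    "station_layout",
    "gen_station_series",
    "gen_population",
    "gen_baseline_rates",
    "gen_cost_and_risk_inputs",
    "write_inputs",
    "load_reference_tables",
]

MORTALITY_ENDPOINTS = ("IHD", "stroke", "LC", "COPD")
MORBIDITY_ENDPOINTS = ("RHA", "CHA", "CB", "AA", "REV")

# annual city-mean targets, ug/m3 (CO in mg/m3); PM2.5 endpoints are the
# study period's published city means, the rest interpolate endpoints chosen
# to match the published 2013->2017 percent changes
_DEFAULT_TARGETS: dict[tuple[str, int], float] = {}
for _pollutant, _series in {
    "PM2.5": (110.0, 97.0, 85.0, 73.0, 63.0),
    "PM10": (184.0, 166.0, 150.0, 135.0, 121.0),
    "SO2": (120.0, 85.0, 62.0, 45.0, 33.0),
    "NO2": (60.0, 55.0, 51.0, 47.0, 43.0),
    "CO": (1.60, 1.45, 1.31, 1.19, 1.07),
    "O3": (155.0, 160.0, 165.0, 171.0, 177.0),
}.items():
    for _year, _value in zip(range(2013, 2018), _series):
        _DEFAULT_TARGETS[(_pollutant, _year)] = _value

# relative size of each endpoint's baseline rate against its kind's scale
_RATE_MULTIPLIER = {
    "IHD": 1.0, "stroke": 1.5, "LC": 0.25, "COPD": 0.35,
    "RHA": 1.6, "CHA": 1.4, "CB": 1.2, "AA": 1.3, "REV": 0.4,
}

# default per-case unit costs, US$: willingness-to-pay for mortality,
# cost-of-illness for morbidity
_DEFAULT_COSTS = {
    "IHD": (134000.0, "WTP"), "stroke": (139000.0, "WTP"),
    "LC": (134000.0, "WTP"), "COPD": (134000.0, "WTP"),
    "RHA": (1560.0, "COI"), "CHA": (2370.0, "COI"),
    "CB": (7150.0, "COI"), "AA": (8.0, "COI"), "REV": (74.0, "COI"),
}

# published per-10-ug/m3 morbidity relative risks with 95% CIs
_DEFAULT_RISK_COEFFICIENTS = [
    ("RHA", 1.022, 1.013, 1.032),
    ("CHA", 1.013, 1.007, 1.019),
    ("CB", 1.029, 1.014, 1.044),
    ("AA", 1.021, 1.015, 1.028),
    ("REV", 1.010, 1.005, 1.016),
]

# editable default GEMM curve parameters per mortality cause: the source
# publication's exact (theta, mu, tau, r) sets are not reproduced here, so
# these are plausible-magnitude stand-ins shipped as data, not constants
_DEFAULT_GEMM = [
    # cause, theta, theta_se, mu, tau, r, f_form
    ("IHD", 0.2969, 0.01787, 12.0, 0.40, 100.0, "log1p"),
    ("stroke", 0.2720, 0.07697, 16.0, 0.40, 100.0, "log1p"),
    ("LC", 0.2942, 0.06147, 9.0, 0.30, 100.0, "log1p"),
    ("COPD", 0.2510, 0.06762, 7.0, 0.30, 100.0, "log1p"),
    ("NCD+LRI", 0.1430, 0.01807, 15.5, 0.37, 100.0, "log1p"),
]

_SEASONAL_PEAK_DOY = {"O3": 196}  # Jul 15; all other pollutants peak Jan 15
_DEFAULT_PEAK_DOY = 15


def _default_years() -> tuple[int, ...]:
    return tuple(range(2013, 2018))


def _default_unmonitored() -> dict[int, tuple[str, ...]]:
    # four outlying districts had no station before the 2016 expansion
    return {2016: ("D07", "D08", "D09", "D10")}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study city.

    ``stations_per_phase`` maps a starting year to the station count active
    from that year onward; ``unmonitored_districts_before`` maps a year to the
    districts that have no station in any earlier year.
    """

    seed: int = 0
    years: tuple[int, ...] = field(default_factory=_default_years)
    n_districts: int = 10
    stations_per_phase: Mapping[int, int] = field(
        default_factory=lambda: {2013: 15, 2016: 32}
    )
    district_population_mean: float = 700_000.0
    city_population_start: float = 7_000_000.0
    city_population_end: float = 7_300_000.0
    pollutant_annual_targets: Mapping[tuple[str, int], float] = field(
        default_factory=lambda: dict(_DEFAULT_TARGETS)
    )
    seasonal_amplitude_fraction: float = 0.4
    noise_cv: float = 0.3
    unmonitored_districts_before: Mapping[int, tuple[str, ...]] = field(
        default_factory=_default_unmonitored
    )
    mortality_rate_scale: float = 0.001
    morbidity_rate_scale: float = 0.005
    year_specific_rates: bool = False

    def __post_init__(self) -> None:
        if not self.years:
            raise ValueError("years must be non-empty")
        if not 0 <= self.seasonal_amplitude_fraction < 1:
            raise ValueError("seasonal_amplitude_fraction must be in [0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if any(n < 1 for n in self.stations_per_phase.values()):
            raise ValueError("station counts must be >= 1")
        if self.n_districts < 1:
            raise ValueError("n_districts must be >= 1")

    @property
    def districts(self) -> tuple[str, ...]:
        return tuple(f"D{i + 1:02d}" for i in range(self.n_districts))

    def stations_active(self, year: int) -> int:
        starts = sorted(y for y in self.stations_per_phase if y <= year)
        if not starts:
            raise ValueError(f"no station phase covers year {year}")
        return self.stations_per_phase[starts[-1]]

    def unmonitored(self, year: int) -> tuple[str, ...]:
        out: set[str] = set()
        for boundary, districts in self.unmonitored_districts_before.items():
            if year < boundary:
                out.update(districts)
        return tuple(sorted(out))

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


def station_layout(config: SimulationConfig) -> pd.DataFrame:
    """Station roster: id, host district, first year active.

    The initial network covers only the always-monitored districts
    (round-robin); the expansion phase adds stations starting with the
    previously unmonitored districts so every district is covered afterwards.
    """
    phases = sorted(config.stations_per_phase.items())
    ever_unmonitored: set[str] = set()
    for districts in config.unmonitored_districts_before.values():
        ever_unmonitored.update(districts)
    core = [d for d in config.districts if d not in ever_unmonitored] or list(config.districts)

    rows: list[tuple[str, str, int]] = []
    n_existing = 0
    for phase_year, count in phases:
        n_new = count - n_existing
        if n_new < 0:
            raise ValueError("station counts must be non-decreasing across phases")
        if n_existing == 0:
            hosts = core
        else:
            # expansion: unmonitored districts first, then everyone
            hosts = sorted(ever_unmonitored) + list(config.districts)
        for i in range(n_new):
            sid = f"S{n_existing + i + 1:02d}"
            rows.append((sid, hosts[i % len(hosts)], phase_year))
        n_existing = count
    return pd.DataFrame(rows, columns=["station_id", "district_id", "active_from"])


def _seasonal_factor(year: int, pollutant: str, amplitude: float) -> np.ndarray:
    """Daily multiplicative seasonal factor, normalized to mean exactly 1.

    Cosine with peak on Jan 15 (Jul 15 for O3); the normalization keeps the
    noise-free annual mean equal to the configured target.
    """
    n_days = 366 if calendar.isleap(year) else 365
    doy = np.arange(1, n_days + 1)
    peak = _SEASONAL_PEAK_DOY.get(pollutant, _DEFAULT_PEAK_DOY)
    s = 1.0 + amplitude * np.cos(2.0 * np.pi * (doy - peak) / 365.25)
    return s / s.mean()


def gen_station_series(config: SimulationConfig) -> pd.DataFrame:
    """Daily station records: one row per station x day x pollutant.

    ``value = target * seasonal(day) * lognormal_noise`` with the lognormal
    scaled to unit mean, so the expected annual city mean is the configured
    target; values are truncated at zero.
    """
    rng = config._rng(1)
    layout = station_layout(config)
    sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))

    parts = []
    for year in config.years:
        active = layout.loc[layout["active_from"] <= year]
        dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        n_days = len(dates)
        n_stations = len(active)
        for pollutant in POLLUTANTS:
            target = config.pollutant_annual_targets.get((pollutant, year))
            if target is None:
                continue
            seasonal = _seasonal_factor(year, pollutant, config.seasonal_amplitude_fraction)
            if sigma > 0:
                noise = np.exp(
                    rng.normal(0.0, sigma, size=(n_stations, n_days)) - 0.5 * sigma**2
                )
            else:
                noise = np.ones((n_stations, n_days))
            values = np.maximum(target * seasonal[None, :] * noise, 0.0)
            parts.append(
                pd.DataFrame(
                    {
                        "station_id": np.repeat(active["station_id"].to_numpy(), n_days),
                        "district_id": np.repeat(active["district_id"].to_numpy(), n_days),
                        "date": np.tile(dates.strftime("%Y-%m-%d"), n_stations),
                        "pollutant": pollutant,
                        "value": values.ravel(),
                    }
                )
            )
    return pd.concat(parts, ignore_index=True)


def gen_population(config: SimulationConfig) -> pd.DataFrame:
    """District populations per year; city total grows linearly over the period.

    District shares are drawn once per run (lognormal, normalized), then held
    fixed while the city total interpolates start -> end.
    """
    rng = config._rng(2)
    weights = np.exp(rng.normal(0.0, 0.25, size=config.n_districts))
    weights /= weights.sum()
    years = sorted(config.years)
    span = max(len(years) - 1, 1)
    rows = []
    for i, year in enumerate(years):
        total = config.city_population_start + (
            config.city_population_end - config.city_population_start
        ) * (i / span)
        for district, w in zip(config.districts, weights):
            rows.append((district, year, float(total * w)))
    return pd.DataFrame(rows, columns=["district_id", "year", "population"])


def gen_baseline_rates(
    config: SimulationConfig,
    endpoints: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Baseline event rates (events per person-year) per endpoint, district, year.

    Rates are ``scale * endpoint_multiplier * district_jitter`` with a ~10%
    lognormal jitter drawn once per endpoint x district; by default they are
    held constant across years (benefit attribution varies exposure, not
    rates). Set ``year_specific_rates=True`` for an additional small yearly
    perturbation.
    """
    all_endpoints = MORTALITY_ENDPOINTS + MORBIDITY_ENDPOINTS
    if endpoints is None:
        endpoints = all_endpoints
    unknown = sorted(set(endpoints) - set(all_endpoints))
    if unknown:
        raise ValueError(f"unknown endpoint labels: {', '.join(unknown)}")

    rng = config._rng(3)
    years = sorted(config.years)
    rows = []
    for endpoint in all_endpoints:  # draw in fixed order for determinism
        kind = "mortality" if endpoint in MORTALITY_ENDPOINTS else "morbidity"
        scale = (
            config.mortality_rate_scale if kind == "mortality" else config.morbidity_rate_scale
        )
        jitter = np.exp(rng.normal(0.0, 0.1, size=config.n_districts))
        yearly = (
            np.exp(rng.normal(0.0, 0.03, size=(len(years), config.n_districts)))
            if config.year_specific_rates
            else np.ones((len(years), config.n_districts))
        )
        if endpoint not in endpoints:
            continue
        base = scale * _RATE_MULTIPLIER[endpoint] * jitter
        for yi, year in enumerate(years):
            rates = np.clip(base * yearly[yi], 1e-9, 0.999999)
            for district, rate in zip(config.districts, rates):
                rows.append((endpoint, kind, district, year, float(rate)))
    return pd.DataFrame(rows, columns=["endpoint", "kind", "district_id", "year", "rate"])


def gen_cost_and_risk_inputs(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Default unit costs, morbidity risk coefficients, and GEMM parameters.

    The five morbidity relative risks are the published per-10-ug/m3 values
    with reference concentration 10 ug/m3; the GEMM table carries one
    parameter set per mortality cause (plus the combined NCD+LRI curve,
    unused by default).
    """
    costs = pd.DataFrame(
        [(e, c, m) for e, (c, m) in _DEFAULT_COSTS.items()],
        columns=["endpoint", "unit_cost_usd", "method"],
    )
    risk = pd.DataFrame(
        _DEFAULT_RISK_COEFFICIENTS,
        columns=["endpoint", "rr_central", "rr_low", "rr_high"],
    )
    risk["delta_c"] = 10.0
    risk["c0"] = 10.0
    gemm = pd.DataFrame(
        _DEFAULT_GEMM,
        columns=["cause", "theta", "theta_se", "mu", "tau", "r", "f_form"],
    )
    gemm["counterfactual"] = 2.4
    return costs, risk, gemm


def write_inputs(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write every pipeline input CSV; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    costs, risk, gemm = gen_cost_and_risk_inputs(config)
    tables = {
        "stations": gen_station_series(config),
        "population": gen_population(config),
        "rates": gen_baseline_rates(config),
        "costs": costs,
        "risk_coefficients": risk,
        "gemm_params": gemm,
    }
    paths = {}
    for name, frame in tables.items():
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths


class ReferenceTables(NamedTuple):
    """Published city-level central estimates and CI bounds, as shipped data."""

    burden: pd.DataFrame
    economics: pd.DataFrame
    summary: pd.DataFrame


def load_reference_tables() -> ReferenceTables:
    """Load the published burden and economic tables used for aggregation checks.

    Returns three frames — attributable counts, monetary values (US$), and
    the headline summary figures — each with columns
    ``endpoint, kind, label, central, low, high``.
    """
    ref = resources.files("aqhia").joinpath("data/reference_tables.csv")
    with resources.as_file(ref) as path:
        raw = pd.read_csv(path)
    expected = {"section", "endpoint", "kind", "label", "central", "low", "high"}
    if not expected.issubset(raw.columns):
        raise ValueError("reference tables fixture is corrupt: missing columns")
    cols = ["endpoint", "kind", "label", "central", "low", "high"]
    return ReferenceTables(
        burden=raw.loc[raw["section"] == "burden", cols].reset_index(drop=True),
        economics=raw.loc[raw["section"] == "economics", cols].reset_index(drop=True),
        summary=raw.loc[raw["section"] == "summary", cols].reset_index(drop=True),
    )
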