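"""Attributable burden, year-on-year health benefits, and scenario projections.

The health impact for one endpoint and spatial unit is

    HI = [(RR - 1) / RR] * P * Pop

with RR the GEMM hazard ratio (mortality) or log-linear relative risk
(morbidity) at the unit's annual PM2.5 exposure, P the baseline event rate
and Pop the exposed population. City totals sum the unit-level impacts;
confidence bounds rerun the identical calculation at the low/high risk bound.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

import pandas as pd

from .exposure import CITY
from .risk import (
    BOUNDS,
    GemmParameterSet,
    RiskCoefficient,
    attributable_fraction,
    gemm_hazard_ratio,
    loglinear_rr,
)

__all__ = [
    "ScenarioSpec",
    "health_impact",
    "compute_burden",
    "scenario_burden",
    "benefit_between",
    "percent_reduction",
    "totals_by_kind",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """A counterfactual air-quality scenario: uniform PM2.5 target for all units."""

    name: str
    pm25_target: float

    def __post_init__(self) -> None:
        if self.pm25_target < 0:
            raise ValueError("pm25_target must be >= 0")


def health_impact(rr: float, rate: float, population: float) -> float:
    """Attributable events: ``AF(rr) * rate * population`` (kept as a real)."""
    if not 0 <= rate <= 1:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    if population <= 0:
        raise ValueError(f"population must be > 0, got {population}")
    return attributable_fraction(rr) * rate * population


def _rr_for(
    endpoint: str,
    kind: str,
    concentration: float,
    gemm_params: Mapping[str, GemmParameterSet],
    risk_coeffs: Mapping[str, RiskCoefficient],
    bound: str,
) -> float:
    if kind == "mortality":
        return gemm_hazard_ratio(concentration, gemm_params[endpoint], bound)
    return loglinear_rr(concentration, risk_coeffs[endpoint], bound)


def compute_burden(
    exposures: pd.DataFrame,
    rates: pd.DataFrame,
    populations: pd.DataFrame,
    gemm_params: Mapping[str, GemmParameterSet],
    risk_coeffs: Mapping[str, RiskCoefficient],
    year: int,
    label: str | None = None,
    pm25_override: float | None = None,
) -> pd.DataFrame:
    """City-total attributable burden per endpoint for one year (or scenario).

    Parameters
    ----------
    exposures
        Output of :func:`aqhia.exposure.annual_exposure_table` (must contain
        PM2.5 rows for the requested year).
    rates
        Columns ``endpoint, kind, district_id, year, rate`` (district_id may
        be ``CITY`` for city-level rates).
    populations
        Columns ``district_id, year, population``.
    gemm_params, risk_coeffs
        Risk specifications keyed by endpoint label.
    pm25_override
        If given, every unit's PM2.5 exposure is replaced by this value
        (scenario projection).

    Returns
    -------
    One row per endpoint: ``endpoint, kind, label, central, low, high, af``
    where ``af`` is the implied city-level attributable fraction
    (central events / total expected events).
    """
    rsub = rates.loc[rates["year"] == year]
    if rsub.empty:
        raise ValueError(f"no baseline rates for year {year}")
    missing = sorted(
        set(rsub.loc[rsub["kind"] == "mortality", "endpoint"]) - set(gemm_params)
    ) + sorted(set(rsub.loc[rsub["kind"] == "morbidity", "endpoint"]) - set(risk_coeffs))
    if missing:
        raise ValueError(f"endpoints without a risk specification: {', '.join(missing)}")

    esub = exposures.loc[
        (exposures["year"] == year) & (exposures["pollutant"] == "PM2.5")
    ]
    conc = dict(zip(esub["unit_id"], esub["mean"]))
    psub = populations.loc[populations["year"] == year]
    pop = dict(zip(psub["district_id"], psub["population"]))
    if CITY not in pop:
        pop[CITY] = float(psub["population"].sum())

    units_missing = sorted(set(rsub["district_id"]) - set(conc)) if pm25_override is None else []
    if units_missing:
        raise ValueError(f"no PM2.5 exposure for units: {', '.join(units_missing)}")

    rows = []
    for (endpoint, kind), part in rsub.groupby(["endpoint", "kind"], sort=True):
        events = {b: 0.0 for b in BOUNDS}
        expected = 0.0
        for row in part.itertuples(index=False):
            c = pm25_override if pm25_override is not None else conc[row.district_id]
            population = pop[row.district_id]
            expected += row.rate * population
            for bound in BOUNDS:
                rr = _rr_for(endpoint, kind, c, gemm_params, risk_coeffs, bound)
                events[bound] += health_impact(rr, row.rate, population)
        rows.append(
            (
                endpoint,
                kind,
                label or str(year),
                events["central"],
                min(events["low"], events["central"]),
                max(events["high"], events["central"]),
                events["central"] / expected if expected > 0 else 0.0,
            )
        )
    return pd.DataFrame(
        rows, columns=["endpoint", "kind", "label", "central", "low", "high", "af"]
    )


def scenario_burden(
    rates: pd.DataFrame,
    populations: pd.DataFrame,
    gemm_params: Mapping[str, GemmParameterSet],
    risk_coeffs: Mapping[str, RiskCoefficient],
    scenario: ScenarioSpec,
    base_year: int,
) -> pd.DataFrame:
    """Burden with every unit's PM2.5 set to the scenario target.

    Baseline rates and populations are held at ``base_year``'s values.
    """
    return compute_burden(
        exposures=pd.DataFrame(columns=["unit_id", "year", "pollutant", "mean"]),
        rates=rates,
        populations=populations,
        gemm_params=gemm_params,
        risk_coeffs=risk_coeffs,
        year=base_year,
        label=scenario.name,
        pm25_override=scenario.pm25_target,
    )


def benefit_between(
    burden_ref: pd.DataFrame, burden_new: pd.DataFrame, label: str = "benefit"
) -> pd.DataFrame:
    """Health benefit per endpoint: reference burden minus new burden.

    Central benefits difference the central estimates; CI bounds difference
    bound-wise and are then min/max-ordered so low <= central <= high. (The
    published per-endpoint benefit CIs are not derivable from the per-year
    CIs by any stated rule; this bound-wise convention is this package's
    declared method.)
    """
    ref = burden_ref.set_index("endpoint")
    new = burden_new.set_index("endpoint")
    if set(ref.index) != set(new.index):
        raise ValueError(
            "endpoint mismatch between burden tables: "
            f"{sorted(set(ref.index) ^ set(new.index))}"
        )
    rows = []
    for endpoint in ref.index:
        central = ref.at[endpoint, "central"] - new.at[endpoint, "central"]
        d_low = ref.at[endpoint, "low"] - new.at[endpoint, "low"]
        d_high = ref.at[endpoint, "high"] - new.at[endpoint, "high"]
        low = min(d_low, d_high, central)
        high = max(d_low, d_high, central)
        rows.append((endpoint, ref.at[endpoint, "kind"], label, central, low, high))
    return pd.DataFrame(rows, columns=["endpoint", "kind", "label", "central", "low", "high"])


def percent_reduction(burden_ref: float, burden_scenario: float) -> float:
    """Percent reduction vs a reference burden, reported to 2 decimals."""
    if burden_ref <= 0:
        raise ValueError(f"reference burden must be > 0, got {burden_ref}")
    return round(100.0 * (burden_ref - burden_scenario) / burden_ref, 2)


def totals_by_kind(burden: pd.DataFrame) -> pd.DataFrame:
    """Sum central/low/high over endpoints within each (kind, label)."""
    return (
        burden.groupby(["kind", "label"], sort=True)[["central", "low", "high"]]
        .sum()
        .reset_index()
    )
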