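"""Monetary valuation of attributable burdens and health benefits.

Mortality endpoints are valued by willingness-to-pay (WTP) per statistical
case; morbidity endpoints by cost-of-illness (COI) per case. Unit costs
borrowed from another region are rescaled by the ratio of GDP per capita.
All currency is nominal US$ of a declared reference year.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "UnitCost",
    "adjust_unit_cost",
    "monetize",
    "gdp_share",
    "unit_costs_from_frame",
]


@dataclass(frozen=True)
class UnitCost:
    """Per-case cost of one health endpoint, US$."""

    endpoint: str
    cost_per_case: float
    method: str = "COI"  # WTP for mortality, COI for morbidity
    source_region: str = ""
    reference_year: int | None = None

    def __post_init__(self) -> None:
        if self.cost_per_case <= 0:
            raise ValueError(f"{self.endpoint}: cost_per_case must be > 0")


def adjust_unit_cost(
    source_cost: float, gdp_pc_target: float, gdp_pc_source: float
) -> float:
    """Rescale a borrowed unit cost by the GDP-per-capita ratio."""
    if min(source_cost, gdp_pc_target, gdp_pc_source) <= 0:
        raise ValueError("source_cost and both GDP-per-capita values must be > 0")
    return source_cost * gdp_pc_target / gdp_pc_source


def unit_costs_from_frame(frame: pd.DataFrame) -> dict[str, UnitCost]:
    """Build ``{endpoint: UnitCost}`` from a costs table."""
    return {
        row.endpoint: UnitCost(
            endpoint=row.endpoint,
            cost_per_case=float(row.unit_cost_usd),
            method=getattr(row, "method", "COI"),
        )
        for row in frame.itertuples(index=False)
    }


def monetize(
    burden: pd.DataFrame, costs: Mapping[str, UnitCost]
) -> pd.DataFrame:
    """Value a burden or benefit table: ``value = events * cost_per_case``.

    Input needs columns ``endpoint, kind, label, central, low, high`` (events);
    output carries the same grid in US$. Bounds inherit the events' bounds.
    """
    missing = sorted(set(burden["endpoint"]) - set(costs))
    if missing:
        raise ValueError(f"endpoints without a unit cost: {', '.join(missing)}")
    out = burden[["endpoint", "kind", "label"]].copy()
    per_case = burden["endpoint"].map(lambda e: costs[e].cost_per_case)
    for col in ("central", "low", "high"):
        out[f"{col}_usd"] = burden[col] * per_case
    return out


def gdp_share(total_benefit: float, gdp: float) -> float:
    """Benefit as a percentage of GDP, rendered to 2 decimals."""
    if gdp <= 0:
        raise ValueError(f"gdp must be > 0, got {gdp}")
    return round(100.0 * total_benefit / gdp, 2)
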