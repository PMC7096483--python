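"""Monetize burdens and benefits; express total benefits as a GDP share.

Mortality is valued by willingness-to-pay per statistical case, morbidity by
cost of illness per case. Writes results/economics.csv and prints the
rendered burden/benefit/economics grids.
"""

from pathlib import Path

import pandas as pd

from aqhia.report import render_tables
from aqhia.valuation import gdp_share, monetize, unit_costs_from_frame

ROOT = Path(__file__).resolve().parents[1] / "results"
GDP_2017_USD = 108.4e9  # study city's gross domestic product in 2017

if __name__ == "__main__":
    burden = pd.read_csv(ROOT / "burden.csv")
    benefits = pd.read_csv(ROOT / "benefits.csv")
    costs = unit_costs_from_frame(pd.read_csv(ROOT / "inputs" / "costs.csv"))
    economics = pd.concat(
        [monetize(burden, costs), monetize(benefits, costs)], ignore_index=True
    )
    economics.to_csv(ROOT / "economics.csv", index=False)

    print(render_tables(burden, benefits, economics))
    total_benefit = economics.query("label == 'benefit'")["central_usd"].sum()
    scenario_benefit = economics.query("label == 'benefit_grade2_15'")["central_usd"].sum()
    print(f"total 2017-vs-2013 benefit: US$ {total_benefit / 1e6:,.1f} M "
          f"({gdp_share(total_benefit, GDP_2017_USD):.2f}% of 2017 GDP)")
    print(f"total scenario benefit:     US$ {scenario_benefit / 1e6:,.1f} M "
          f"({gdp_share(scenario_benefit, GDP_2017_USD):.2f}% of 2017 GDP)")
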