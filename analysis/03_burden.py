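"""Attributable burden in 2013 and 2017, the 15 ug/m3 scenario, and benefits.

Mortality uses GEMM hazard ratios, morbidity log-linear relative risks;
benefits difference the comparison year (and scenario) against 2013.
Writes results/burden.csv and results/benefits.csv.
"""

from pathlib import Path

import pandas as pd

from aqhia.burden import (
    ScenarioSpec,
    benefit_between,
    compute_burden,
    percent_reduction,
    scenario_burden,
    totals_by_kind,
)
from aqhia.risk import gemm_params_from_frame, risk_coefficients_from_frame

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    inputs = ROOT / "inputs"
    exposures = pd.read_csv(ROOT / "annual_exposure.csv")
    rates = pd.read_csv(inputs / "rates.csv")
    populations = pd.read_csv(inputs / "population.csv")
    gemm = gemm_params_from_frame(pd.read_csv(inputs / "gemm_params.csv"))
    coeffs = risk_coefficients_from_frame(pd.read_csv(inputs / "risk_coefficients.csv"))

    b13 = compute_burden(exposures, rates, populations, gemm, coeffs, 2013)
    b17 = compute_burden(exposures, rates, populations, gemm, coeffs, 2017)
    scen = scenario_burden(rates, populations, gemm, coeffs,
                           ScenarioSpec("grade2_15", 15.0), 2013)
    burden = pd.concat([b13, b17, scen], ignore_index=True)
    burden.to_csv(ROOT / "burden.csv", index=False)

    benefits = pd.concat(
        [benefit_between(b13, b17, "benefit"),
         benefit_between(b13, scen, "benefit_grade2_15")],
        ignore_index=True,
    )
    benefits.to_csv(ROOT / "benefits.csv", index=False)

    print("attributable totals (central):")
    print(totals_by_kind(burden).round(0).to_string(index=False))
    print("\nbenefit totals (central):")
    print(totals_by_kind(benefits).round(0).to_string(index=False))
    mort13 = b13.query("kind == 'mortality'")["central"].sum()
    mort_sc = scen.query("kind == 'mortality'")["central"].sum()
    print(f"\nscenario mortality reduction vs 2013: "
          f"{percent_reduction(mort13, mort_sc):.2f}%")
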