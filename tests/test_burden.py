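"""Attributable burden, benefits, and scenarios against brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from aqhia.burden import (
    ScenarioSpec,
    benefit_between,
    compute_burden,
    health_impact,
    percent_reduction,
    scenario_burden,
    totals_by_kind,
)
from aqhia.risk import (
    GemmParameterSet,
    RiskCoefficient,
    gemm_hazard_ratio,
    loglinear_rr,
)

RHA = RiskCoefficient("RHA", 1.022, 1.013, 1.032, delta_c=10.0, c0=10.0)
CB = RiskCoefficient("CB", 1.029, 1.014, 1.044, delta_c=10.0, c0=10.0)
IHD = GemmParameterSet("IHD", 0.012, 0.002, 10.0, 0.5, 100.0, "linear", 2.4)


def _exposures(unit_means: dict[str, float], year=2013) -> pd.DataFrame:
    rows = [(u, year, "PM2.5", m, 1, False) for u, m in unit_means.items()]
    city = float(np.mean(list(unit_means.values())))
    rows.append(("CITY", year, "PM2.5", city, len(unit_means), False))
    return pd.DataFrame(
        rows, columns=["unit_id", "year", "pollutant", "mean", "n_station_years", "imputed"]
    )


def _rates(entries, year=2013) -> pd.DataFrame:
    return pd.DataFrame(
        [(e, k, u, year, r) for e, k, u, r in entries],
        columns=["endpoint", "kind", "district_id", "year", "rate"],
    )


def _pop(units: dict[str, float], year=2013) -> pd.DataFrame:
    return pd.DataFrame(
        [(u, year, p) for u, p in units.items()],
        columns=["district_id", "year", "population"],
    )


class TestHealthImpact:
    def test_null_effect(self):
        assert health_impact(1.0, 0.01, 7e6) == 0.0

    def test_rha_at_110(self):
        expected = (1 - 1.022**-10) * 0.01 * 7e6  # independent arithmetic
        assert health_impact(1.022**10, 0.01, 7e6) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(13689.54, abs=0.01)

    def test_saturates_at_expected_events(self):
        assert health_impact(1e9, 0.01, 7e6) == pytest.approx(70_000.0, rel=1e-6)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            health_impact(1.1, 1.5, 7e6)
        with pytest.raises(ValueError):
            health_impact(1.1, 0.01, 0.0)


class TestComputeBurden:
    def test_reference_level_exposure_gives_zero_burden(self):
        exp = _exposures({"D01": 10.0})
        rates = _rates([("RHA", "morbidity", "D01", 0.01), ("IHD", "mortality", "D01", 0.001)])
        ihd = GemmParameterSet("IHD", 0.012, 0.002, 10.0, 0.5, 100.0, "linear",
                               counterfactual=10.0)
        out = compute_burden(exp, rates, _pop({"D01": 7e6}), {"IHD": ihd}, {"RHA": RHA}, 2013)
        assert (out["central"] == 0.0).all()
        assert (out["low"] == 0.0).all() and (out["high"] == 0.0).all()

    def test_single_unit_rha_matches_arithmetic_oracle(self):
        exp = _exposures({"D01": 110.0})
        rates = _rates([("RHA", "morbidity", "D01", 0.01)])
        out = compute_burden(exp, rates, _pop({"D01": 7e6}), {}, {"RHA": RHA}, 2013)
        expected = (1 - 1.022**-10) * 0.01 * 7e6
        assert out.loc[0, "central"] == pytest.approx(expected, rel=1e-12)
        assert out.loc[0, "af"] == pytest.approx(1 - 1.022**-10, rel=1e-12)

    def test_burden_linear_in_population(self):
        exp = _exposures({"D01": 90.0, "D02": 120.0})
        rates = _rates(
            [("RHA", "morbidity", u, 0.01) for u in ("D01", "D02")]
            + [("IHD", "mortality", u, 0.001) for u in ("D01", "D02")]
        )
        base = compute_burden(exp, rates, _pop({"D01": 5e5, "D02": 8e5}),
                              {"IHD": IHD}, {"RHA": RHA}, 2013)
        doubled = compute_burden(exp, rates, _pop({"D01": 1e6, "D02": 1.6e6}),
                                 {"IHD": IHD}, {"RHA": RHA}, 2013)
        for col in ("central", "low", "high"):
            assert np.allclose(doubled[col], 2 * base[col], rtol=1e-12)

    def test_missing_risk_spec_lists_endpoints(self):
        exp = _exposures({"D01": 80.0})
        rates = _rates([("CB", "morbidity", "D01", 0.01), ("IHD", "mortality", "D01", 0.001)])
        with pytest.raises(ValueError, match="CB"):
            compute_burden(exp, rates, _pop({"D01": 1e6}), {"IHD": IHD}, {"RHA": RHA}, 2013)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle_on_small_instances(self, seed):
        """Literal per-unit reimplementation agrees to >= 10 significant digits."""
        rng = np.random.default_rng(seed)
        units = [f"D{i:02d}" for i in range(rng.integers(1, 4))]
        means = {u: float(rng.uniform(15, 150)) for u in units}
        pops = {u: float(rng.uniform(1e5, 2e6)) for u in units}
        rate_rows, oracle = [], {}
        for endpoint, kind, spec in (
            ("RHA", "morbidity", RHA), ("CB", "morbidity", CB), ("IHD", "mortality", IHD),
        ):
            total = 0.0
            for u in units:
                rate = float(rng.uniform(1e-4, 0.02))
                rate_rows.append((endpoint, kind, u, rate))
                if kind == "morbidity":
                    rr = loglinear_rr(means[u], spec)
                else:
                    rr = gemm_hazard_ratio(means[u], spec)
                total += (rr - 1) / rr * rate * pops[u]
            oracle[endpoint] = total
        out = compute_burden(
            _exposures(means), _rates(rate_rows), _pop(pops), {"IHD": IHD},
            {"RHA": RHA, "CB": CB}, 2013,
        ).set_index("endpoint")
        for endpoint, expected in oracle.items():
            assert out.at[endpoint, "central"] == pytest.approx(expected, rel=1e-10)


class TestScenarioBurden:
    RATES = _rates([("RHA", "morbidity", "D01", 0.01), ("CB", "morbidity", "D01", 0.005)])
    POP = _pop({"D01": 7e6})

    def test_target_at_reference_zeroes_morbidity(self):
        out = scenario_burden(self.RATES, self.POP, {}, {"RHA": RHA, "CB": CB},
                              ScenarioSpec("ref", 10.0), 2013)
        assert (out["central"] == 0.0).all()

    def test_target_15_matches_arithmetic_oracle(self):
        out = scenario_burden(self.RATES, self.POP, {}, {"RHA": RHA, "CB": CB},
                              ScenarioSpec("grade2", 15.0), 2013)
        expected = (1 - math.exp(-math.log(1.022) / 10 * 5)) * 0.01 * 7e6
        assert out.set_index("endpoint").at["RHA", "central"] == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(757.52, abs=0.01)

    def test_identity_scenario_equals_observed_burden(self):
        exp = _exposures({"D01": 110.0})
        observed = compute_burden(exp, self.RATES, self.POP, {}, {"RHA": RHA, "CB": CB}, 2013)
        scen = scenario_burden(self.RATES, self.POP, {}, {"RHA": RHA, "CB": CB},
                               ScenarioSpec("obs", 110.0), 2013)
        assert np.allclose(observed[["central", "low", "high"]],
                           scen[["central", "low", "high"]])

    def test_lower_target_never_increases_burden(self):
        burdens = [
            scenario_burden(self.RATES, self.POP, {}, {"RHA": RHA, "CB": CB},
                            ScenarioSpec(f"t{t}", t), 2013)["central"].sum()
            for t in (120.0, 63.0, 35.0, 15.0, 10.0, 0.0)
        ]
        assert all(a >= b for a, b in zip(burdens, burdens[1:]))

    def test_beta_recovered_from_two_exposure_levels(self):
        """Implied RRs at two synthetic exposure levels recover the known slope."""
        rate, pop = 0.008, 1.2e6
        c1, c2 = 48.0, 97.0
        afs = []
        for c in (c1, c2):
            out = scenario_burden(
                _rates([("RHA", "morbidity", "D01", rate)]), _pop({"D01": pop}),
                {}, {"RHA": RHA}, ScenarioSpec("x", c), 2013,
            )
            afs.append(out.loc[0, "central"] / (rate * pop))
        rr1, rr2 = 1 / (1 - afs[0]), 1 / (1 - afs[1])
        beta_hat = math.log(rr2 / rr1) / (c2 - c1)
        assert beta_hat == pytest.approx(math.log(1.022) / 10, rel=1e-6)


class TestBenefits:
    def test_fixture_style_difference(self):
        ref = pd.DataFrame(
            [("IHD", "mortality", "2013", 4246.0, 3946.0, 4508.0)],
            columns=["endpoint", "kind", "label", "central", "low", "high"],
        )
        new = pd.DataFrame(
            [("IHD", "mortality", "2017", 3577.0, 3282.0, 3846.0)],
            columns=["endpoint", "kind", "label", "central", "low", "high"],
        )
        out = benefit_between(ref, new)
        assert out.loc[0, "central"] == 669.0
        assert out.loc[0, "low"] <= 669.0 <= out.loc[0, "high"]

    def test_self_difference_is_zero(self):
        exp = _exposures({"D01": 90.0})
        rates = _rates([("RHA", "morbidity", "D01", 0.01)])
        b = compute_burden(exp, rates, _pop({"D01": 1e6}), {}, {"RHA": RHA}, 2013)
        out = benefit_between(b, b)
        assert (out[["central", "low", "high"]] == 0.0).all().all()

    def test_endpoint_mismatch_raises(self):
        a = pd.DataFrame([("RHA", "morbidity", "x", 1.0, 0.5, 2.0)],
                         columns=["endpoint", "kind", "label", "central", "low", "high"])
        b = a.assign(endpoint="CB")
        with pytest.raises(ValueError, match="mismatch"):
            benefit_between(a, b)

    def test_total_benefit_equals_difference_of_totals(self):
        exp13 = _exposures({"D01": 110.0, "D02": 95.0}, year=2013)
        exp17 = _exposures({"D01": 63.0, "D02": 58.0}, year=2017)
        rates = pd.concat([
            _rates([("RHA", "morbidity", u, 0.01) for u in ("D01", "D02")], year=y)
            for y in (2013, 2017)
        ])
        pops = pd.concat([_pop({"D01": 1e6, "D02": 2e6}, year=y) for y in (2013, 2017)])
        b13 = compute_burden(exp13, rates, pops, {}, {"RHA": RHA}, 2013)
        b17 = compute_burden(exp17, rates, pops, {}, {"RHA": RHA}, 2017)
        benefit = benefit_between(b13, b17)
        assert benefit["central"].sum() == pytest.approx(
            b13["central"].sum() - b17["central"].sum(), rel=1e-12
        )


class TestPercentReduction:
    @pytest.mark.parametrize(
        "ref,scen,expected", [(6401, 1601, 74.99), (1327, 361, 72.80), (500, 500, 0.0)]
    )
    def test_published_cells_and_identity(self, ref, scen, expected):
        assert percent_reduction(ref, scen) == expected

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_reduction(0.0, 1.0)


def test_totals_by_kind_sums_endpoints():
    frame = pd.DataFrame(
        [
            ("RHA", "morbidity", "2013", 10.0, 5.0, 15.0),
            ("CB", "morbidity", "2013", 20.0, 10.0, 30.0),
            ("IHD", "mortality", "2013", 7.0, 6.0, 8.0),
        ],
        columns=["endpoint", "kind", "label", "central", "low", "high"],
    )
    out = totals_by_kind(frame).set_index("kind")
    assert out.at["morbidity", "central"] == 30.0
    assert out.at["mortality", "high"] == 8.0
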