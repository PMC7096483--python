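"""Concentration-response functions for long-term PM2.5 exposure.

Two families are implemented:

* **GEMM** (Global Exposure Mortality Model) hazard ratios for cause-specific
  mortality, ``HR = exp(theta * f(z) * omega(z))`` where ``z`` is the annual
  PM2.5 concentration above a counterfactual level, ``f`` is either the
  identity or ``log(1 + z)``, and ``omega`` is a logistic weight controlling
  the curvature of the association.
* **Log-linear** relative risks for morbidity endpoints,
  ``RR = exp(beta * (C - C0))`` with ``beta = ln(RR_per_dC) / dC`` derived
  from published relative risks per 10 ug/m3.

Both families return exactly 1 at or below their reference concentration:
no protective effect is ever attributed to sub-reference exposure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GemmParameterSet",
    "RiskCoefficient",
    "logistic_weight",
    "gemm_hazard_ratio",
    "beta_from_rr",
    "loglinear_rr",
    "attributable_fraction",
    "gemm_params_from_frame",
    "risk_coefficients_from_frame",
]

#: default counterfactual PM2.5 concentration for mortality hazard ratios,
#: ug/m3 (lower bound of the exposure range the GEMM curves were fit over)
DEFAULT_COUNTERFACTUAL = 2.4

#: default reference concentration for morbidity relative risks, ug/m3
DEFAULT_C0 = 10.0

F_FORMS = ("linear", "log1p")
BOUNDS = ("low", "central", "high")


@dataclass(frozen=True)
class GemmParameterSet:
    """Shape parameters of one GEMM mortality curve.

    Parameters
    ----------
    cause
        Cause-of-death label (IHD, stroke, LC, COPD or NCD+LRI).
    theta, theta_se
        Log-hazard slope on the transformed concentration scale and its
        standard error; 95% bounds use ``theta +- 1.96 * theta_se``.
    mu
        Location of the logistic weight, ug/m3.
    tau
        Curvature of the logistic weight (unitless; scaled by ``r``).
    r
        Range of pollutant concentrations the curve was fit over, ug/m3.
    f_form
        Concentration transform: ``"linear"`` (f(z) = z) or ``"log1p"``
        (f(z) = log(1 + z)).
    counterfactual
        Concentration below which no excess hazard is attributed, ug/m3.
    """

    cause: str
    theta: float
    theta_se: float
    mu: float
    tau: float
    r: float
    f_form: str = "linear"
    counterfactual: float = DEFAULT_COUNTERFACTUAL

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.r <= 0:
            raise ValueError(f"r must be > 0, got {self.r}")
        if self.counterfactual < 0:
            raise ValueError("counterfactual must be >= 0")
        if self.f_form not in F_FORMS:
            raise ValueError(f"f_form must be one of {F_FORMS}, got {self.f_form!r}")

    def theta_at(self, bound: str) -> float:
        if bound == "central":
            return self.theta
        if bound == "low":
            return self.theta - 1.96 * self.theta_se
        if bound == "high":
            return self.theta + 1.96 * self.theta_se
        raise ValueError(f"bound must be one of {BOUNDS}, got {bound!r}")


@dataclass(frozen=True)
class RiskCoefficient:
    """Published relative risk per ``delta_c`` ug/m3 for one morbidity endpoint."""

    endpoint: str
    rr_central: float
    rr_low: float
    rr_high: float
    delta_c: float = 10.0
    c0: float = DEFAULT_C0

    def __post_init__(self) -> None:
        if not (0 < self.rr_low <= self.rr_central <= self.rr_high):
            raise ValueError(
                f"{self.endpoint}: require 0 < rr_low <= rr_central <= rr_high, "
                f"got ({self.rr_low}, {self.rr_central}, {self.rr_high})"
            )
        if self.delta_c <= 0:
            raise ValueError("delta_c must be > 0")
        if self.c0 < 0:
            raise ValueError("c0 must be >= 0")

    def rr_at(self, bound: str) -> float:
        if bound == "central":
            return self.rr_central
        if bound == "low":
            return self.rr_low
        if bound == "high":
            return self.rr_high
        raise ValueError(f"bound must be one of {BOUNDS}, got {bound!r}")


def logistic_weight(z, mu: float, tau: float, r: float):
    """Logistic weight ``omega(z) = 1 / (1 + exp(-(z - mu) / (tau * r)))``.

    Strictly increasing in ``z``; equals 0.5 at ``z = mu`` and saturates to 1
    for large excess concentrations. ``tau`` and ``r`` must be positive.
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    if r <= 0:
        raise ValueError(f"r must be > 0, got {r}")
    z = np.asarray(z, dtype=float)
    out = 1.0 / (1.0 + np.exp(-(z - mu) / (tau * r)))
    return float(out) if out.ndim == 0 else out


def gemm_hazard_ratio(c: float, params: GemmParameterSet, bound: str = "central") -> float:
    """GEMM hazard ratio at annual PM2.5 concentration ``c`` (ug/m3).

    ``z = max(0, c - counterfactual)``; HR is exactly 1 when ``z = 0``.
    A negative slope at the chosen bound is floored at HR = 1 with a warning:
    protective effects of PM2.5 are not attributed.
    """
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    z = c - params.counterfactual
    if z <= 0:
        return 1.0
    theta = params.theta_at(bound)
    if theta < 0:
        warnings.warn(
            f"{params.cause}: theta at bound {bound!r} is negative "
            f"({theta:.4g}); hazard ratio floored at 1",
            stacklevel=2,
        )
        return 1.0
    fz = z if params.f_form == "linear" else math.log1p(z)
    hr = math.exp(theta * fz * logistic_weight(z, params.mu, params.tau, params.r))
    return max(hr, 1.0)


def beta_from_rr(rr: float, delta_c: float) -> float:
    """Exposure-response slope per ug/m3: ``beta = ln(RR) / delta_c``."""
    if rr <= 0:
        raise ValueError(f"rr must be > 0, got {rr}")
    if delta_c <= 0:
        raise ValueError(f"delta_c must be > 0, got {delta_c}")
    return math.log(rr) / delta_c


def loglinear_rr(c: float, coeff: RiskCoefficient, bound: str = "central") -> float:
    """Log-linear morbidity relative risk at annual PM2.5 concentration ``c``.

    ``RR = exp(beta * max(0, c - c0))`` with ``beta`` derived from the
    endpoint's published RR at the chosen bound. Concentrations at or below
    the reference ``c0`` yield RR = 1 (clamped; no protective effect).
    """
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    excess = c - coeff.c0
    if excess <= 0:
        return 1.0
    beta = beta_from_rr(coeff.rr_at(bound), coeff.delta_c)
    return math.exp(beta * excess)


def attributable_fraction(rr: float) -> float:
    """Population attributable fraction ``(RR - 1) / RR`` for ``RR >= 1``."""
    if rr < 1:
        raise ValueError(f"rr must be >= 1 (clamp upstream), got {rr}")
    return (rr - 1.0) / rr


def gemm_params_from_frame(frame: pd.DataFrame) -> dict[str, GemmParameterSet]:
    """Build ``{cause: GemmParameterSet}`` from a gemm_params table."""
    out: dict[str, GemmParameterSet] = {}
    for row in frame.itertuples(index=False):
        kwargs = dict(
            cause=row.cause,
            theta=float(row.theta),
            theta_se=float(row.theta_se),
            mu=float(row.mu),
            tau=float(row.tau),
            r=float(row.r),
            f_form=str(row.f_form),
        )
        if "counterfactual" in frame.columns:
            kwargs["counterfactual"] = float(row.counterfactual)
        out[row.cause] = GemmParameterSet(**kwargs)
    return out


def risk_coefficients_from_frame(frame: pd.DataFrame) -> dict[str, RiskCoefficient]:
    """Build ``{endpoint: RiskCoefficient}`` from a risk_coefficients table."""
    return {
        row.endpoint: RiskCoefficient(
            endpoint=row.endpoint,
            rr_central=float(row.rr_central),
            rr_low=float(row.rr_low),
            rr_high=float(row.rr_high),
            delta_c=float(row.delta_c),
            c0=float(row.c0),
        )
        for row in frame.itertuples(index=False)
    }
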