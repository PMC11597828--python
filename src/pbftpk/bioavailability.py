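"""Bioavailable fraction F and fraction of dose absorbed F* from oral data alone.

Three estimators, all requiring only an oral profile (no intravenous arm):

* one-stage closed form         F  = kel * tau / (exp(kel * tau) - 1)
* two-stage closed form         F  = (a1 + a2) kel / [ (a1/tau1)(e^{kel tau1} - 1)
                                      + (a2/tau2) e^{kel tau1} (e^{kel tau2} - 1) ]
  where a_i = rate_i * tau_i is the composite F_i D / V_d of stage i
* semi-noncompartmental         F* = (AUC_oral / AUC_hyp.iv)^exponent

The hypothetical-IV-bolus AUC comes from back-extrapolating the post-absorption
(t > tau) log-linear elimination phase of the oral data to t = 0: the intercept
C0 plays the role of the bolus concentration, so AUC_hyp.iv = C0 / kel_hat.
On data exactly consistent with the staged zero-order model, the exponent-1
ratio coincides with the closed forms above; the default exponent is 1/2 and
both are one call away.

All quantities are per central-compartment volume, so doses and volumes of
distribution cancel and never appear.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import linregress

from .models import ConcentrationTimeSeries

__all__ = [
    "TerminalPhaseFit",
    "BioavailabilityEstimate",
    "estimate_F_eq3",
    "estimate_F_eq4",
    "terminal_phase_fit",
    "auc_trapezoid_with_tail",
    "estimate_F_star_eq5",
]


@dataclass(frozen=True)
class TerminalPhaseFit:
    """Log-linear fit of the elimination phase beyond the absorption time.

    intercept is the back-extrapolated hypothetical IV-bolus concentration at
    t = 0 (concentration scale, not log).
    """

    kel_hat: float
    intercept: float
    t_start: float
    n_points: int
    r_squared: float

    def __post_init__(self) -> None:
        if not self.kel_hat > 0:
            raise ValueError("terminal slope must be negative (kel_hat > 0)")
        if not self.intercept > 0:
            raise ValueError("back-extrapolated intercept must be > 0")
        if self.n_points < 3:
            raise ValueError("terminal fit needs >= 3 points")

    @property
    def auc_hypothetical_iv(self) -> float:
        """AUC of the hypothetical IV bolus: intercept / kel_hat."""
        return self.intercept / self.kel_hat


@dataclass(frozen=True)
class BioavailabilityEstimate:
    """A bioavailable-fraction (or fraction-absorbed) estimate with provenance."""

    value: float
    method: str  # "eq3" | "eq4" | "eq5"
    inputs_used: dict[str, float] = field(default_factory=dict)
    exponent_used: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError("bioavailability estimate must be positive")
        if self.method not in ("eq3", "eq4", "eq5"):
            raise ValueError(f"unknown method tag {self.method!r}")


def estimate_F_eq3(kel: float, tau: float) -> BioavailabilityEstimate:
    """One-stage closed form: F = kel*tau / (exp(kel*tau) - 1).

    Strictly decreasing in the product kel*tau; tends to 1 as kel*tau -> 0
    (instantaneous absorption) and to 0 as kel*tau grows.
    """
    if not (kel > 0 and tau > 0):
        raise ValueError(f"kel and tau must be > 0, got kel={kel}, tau={tau}")
    x = kel * tau
    value = x / math.expm1(x)
    return BioavailabilityEstimate(
        value=value, method="eq3", inputs_used={"kel": kel, "tau": tau}
    )


def estimate_F_eq4(
    amount1: float, amount2: float, tau1: float, tau2: float, kel: float
) -> BioavailabilityEstimate:
    """Two-stage closed form for F from the fitted stage composites.

    amount_i = rate_i * tau_i is the composite F_i D / V_d of stage i.  With
    amount2 = 0 this reduces exactly to the one-stage form at tau1; with equal
    stage rates it equals the one-stage form at tau1 + tau2.
    """
    if not (tau1 > 0 and tau2 > 0):
        raise ValueError("stage durations must be > 0")
    if not kel > 0:
        raise ValueError("kel must be > 0")
    if amount1 < 0 or amount2 < 0:
        raise ValueError("stage amounts must be >= 0")
    if amount1 == 0 and amount2 == 0:
        raise ValueError("at least one stage amount must be nonzero")
    denom = (amount1 / tau1) * math.expm1(kel * tau1) + (
        amount2 / tau2
    ) * math.exp(kel * tau1) * math.expm1(kel * tau2)
    value = (amount1 + amount2) * kel / denom
    return BioavailabilityEstimate(
        value=value,
        method="eq4",
        inputs_used={
            "amount1": amount1,
            "amount2": amount2,
            "tau1": tau1,
            "tau2": tau2,
            "kel": kel,
        },
    )


def terminal_phase_fit(series: ConcentrationTimeSeries, tau: float) -> TerminalPhaseFit:
    """Ordinary least squares of ln(concentration) on time for points t > tau.

    All observations strictly beyond the absorption time qualify; nonpositive
    concentrations among them are excluded with a warning.  At least three
    usable points are required.
    """
    mask = series.times > tau
    t_sel = series.times[mask]
    c_sel = series.concentrations[mask]
    n_qualifying = len(t_sel)
    pos = c_sel > 0
    if n_qualifying and not np.all(pos):
        warnings.warn(
            f"excluding {int((~pos).sum())} nonpositive concentration(s) from "
            "the terminal-phase fit",
            stacklevel=2,
        )
    t_sel, c_sel = t_sel[pos], c_sel[pos]
    if len(t_sel) < 3:
        raise ValueError(
            f"terminal-phase fit needs >= 3 positive observations beyond "
            f"tau={tau:g} h, found {len(t_sel)}"
        )
    res = linregress(t_sel, np.log(c_sel))
    kel_hat = -float(res.slope)
    if kel_hat <= 0:
        raise ValueError(
            "terminal phase is not decaying (nonnegative log-linear slope); "
            "cannot back-extrapolate an elimination phase"
        )
    return TerminalPhaseFit(
        kel_hat=kel_hat,
        intercept=float(np.exp(res.intercept)),
        t_start=float(t_sel[0]),
        n_points=int(len(t_sel)),
        r_squared=float(res.rvalue**2),
    )


def auc_trapezoid_with_tail(series: ConcentrationTimeSeries, kel_hat: float) -> float:
    """Linear-trapezoid AUC over the observed range plus the tail C_last/kel_hat."""
    if not kel_hat > 0:
        raise ValueError("kel_hat must be > 0")
    if len(series) < 2:
        raise ValueError("AUC needs at least two observations")
    area = float(np.trapezoid(series.concentrations, series.times))
    return area + float(series.concentrations[-1]) / kel_hat


def estimate_F_star_eq5(
    series: ConcentrationTimeSeries, tau: float, exponent: float = 0.5
) -> BioavailabilityEstimate:
    """Semi-noncompartmental fraction absorbed from the oral profile alone.

    F* = (AUC_oral / AUC_hyp.iv)^exponent, with the hypothetical IV bolus built
    by back-extrapolating the t > tau elimination phase, and the same fitted
    terminal slope closing the oral AUC tail.  Self-contained in oral data.
    """
    tpf = terminal_phase_fit(series, tau)
    auc_hyp = tpf.auc_hypothetical_iv
    assert auc_hyp > 0
    auc_oral = auc_trapezoid_with_tail(series, tpf.kel_hat)
    if auc_oral <= 0:
        raise ValueError("oral AUC is nonpositive; cannot form the ratio")
    value = (auc_oral / auc_hyp) ** exponent
    return BioavailabilityEstimate(
        value=value,
        method="eq5",
        inputs_used={
            "auc_oral": auc_oral,
            "auc_hypothetical_iv": auc_hyp,
            "kel_hat": tpf.kel_hat,
            "intercept": tpf.intercept,
            "tau": tau,
        },
        exponent_used=exponent,
    )
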