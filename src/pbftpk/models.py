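"""Domain types and closed-form forward models for finite-absorption-time PK.

A PBFTPK (physiologically based finite-time pharmacokinetic) model describes
an oral concentration-time profile as one or more successive *zero-order*
(constant-rate) absorption stages feeding a linear one- or two-compartment
disposition model.  Absorption terminates at a finite time tau (the finite
absorption time, F.A.T.), the sum of the stage durations, after which the
profile decays mono- or bi-exponentially.

Rates are expressed per volume of the central compartment (concentration per
hour), so the product rate x duration of a stage is the composite amount
F_i * D / V_d on the concentration scale; no explicit dose or volume of
distribution ever appears.  Time is in hours throughout, with t = 0 the
moment of dose administration.

The classical Bateman function (first-order absorption into a one-compartment
model, implying infinite absorption time) is provided as a comparator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "ConcentrationTimeSeries",
    "InputStage",
    "AbsorptionSchedule",
    "OneCompartmentDisposition",
    "TwoCompartmentDisposition",
    "PBFTPKModel",
    "BatemanModel",
    "concentration_one_compartment",
    "concentration_two_compartment",
    "bateman_concentration",
    "auc_infinity_analytic",
    "cmax_tmax",
]

Disposition = Union["OneCompartmentDisposition", "TwoCompartmentDisposition"]


def _validated_times(t) -> tuple[np.ndarray, bool]:
    """Coerce a time argument to an array of nonnegative floats.

    Returns the array and a flag marking whether the input was scalar.
    """
    scalar = np.isscalar(t) or (isinstance(t, np.ndarray) and t.ndim == 0)
    arr = np.atleast_1d(np.asarray(t, dtype=float))
    if not np.all(np.isfinite(arr)):
        raise ValueError("time values must be finite")
    if np.any(arr < 0):
        raise ValueError("negative time rejected: t = 0 is dose administration")
    return arr, scalar


@dataclass
class ConcentrationTimeSeries:
    """An observed or simulated oral concentration-time profile.

    times are hours (strictly increasing, first >= 0); concentrations are in
    the declared unit (each >= 0, finite).
    """

    times: np.ndarray
    concentrations: np.ndarray
    unit_label: str = "ng/mL"
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.ndim != 1 or self.concentrations.ndim != 1:
            raise ValueError("times and concentrations must be 1-D")
        if len(self.times) != len(self.concentrations):
            raise ValueError(
                f"length mismatch: {len(self.times)} times vs "
                f"{len(self.concentrations)} concentrations"
            )
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.concentrations))):
            raise ValueError("times and concentrations must be finite")
        if len(self.times) and self.times[0] < 0:
            raise ValueError("first time must be >= 0")
        if np.any(np.diff(self.times) <= 0):
            bad = np.nonzero(np.diff(self.times) <= 0)[0]
            raise ValueError(f"times must be strictly increasing (violated after index {bad[0]})")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class InputStage:
    """One zero-order absorption stage: constant input at `rate` for `duration` hours.

    `rate` is concentration per hour (amount per central volume per hour), so
    `amount` = rate * duration lives on the concentration scale and houses the
    composite F_i * D / V_d.
    """

    duration: float
    rate: float

    def __post_init__(self) -> None:
        if not (self.duration > 0 and math.isfinite(self.duration)):
            raise ValueError(f"stage duration must be > 0 h, got {self.duration}")
        if not (self.rate >= 0 and math.isfinite(self.rate)):
            raise ValueError(f"stage rate must be >= 0, got {self.rate}")

    @property
    def amount(self) -> float:
        return self.rate * self.duration


@dataclass(frozen=True)
class AbsorptionSchedule:
    """An ordered sequence of zero-order input stages.

    total_duration (the finite absorption time tau) is the sum of stage
    durations; breakpoints are the cumulative stage end times.
    """

    stages: tuple[InputStage, ...]

    def __init__(self, stages: Sequence[InputStage]):
        stages = tuple(stages)
        if len(stages) == 0:
            raise ValueError("schedule needs at least one stage")
        object.__setattr__(self, "stages", stages)

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    @property
    def durations(self) -> np.ndarray:
        return np.array([s.duration for s in self.stages])

    @property
    def rates(self) -> np.ndarray:
        return np.array([s.rate for s in self.stages])

    @property
    def total_duration(self) -> float:
        """The finite absorption time tau = sum of stage durations (h)."""
        return float(np.sum(self.durations))

    @property
    def breakpoints(self) -> np.ndarray:
        """Cumulative stage end times b_1 < b_2 < ... = tau."""
        return np.cumsum(self.durations)

    @property
    def start_times(self) -> np.ndarray:
        return np.concatenate([[0.0], self.breakpoints[:-1]])

    @property
    def total_amount(self) -> float:
        """Sum r_i * tau_i — the composite F*D/V_d on the concentration scale."""
        return float(np.sum(self.rates * self.durations))


@dataclass(frozen=True)
class OneCompartmentDisposition:
    """First-order elimination from a single well-mixed compartment."""

    kel: float

    def __post_init__(self) -> None:
        if not (self.kel > 0 and math.isfinite(self.kel)):
            raise ValueError(f"kel must be > 0 /h, got {self.kel}")


@dataclass(frozen=True)
class TwoCompartmentDisposition:
    """Central + peripheral compartment, micro-constant parametrization.

    k12: central -> peripheral; k21: peripheral -> central; k10: elimination
    from central.  The hybrid rate constants alpha > beta > 0 follow from
    positivity of the micro-constants.
    """

    k12: float
    k21: float
    k10: float

    def __post_init__(self) -> None:
        for name in ("k12", "k21", "k10"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be > 0 /h, got {v}")

    @property
    def hybrid_constants(self) -> tuple[float, float]:
        """(alpha, beta): fast and slow exponents of the biexponential decay."""
        s = self.k12 + self.k21 + self.k10
        disc = math.sqrt(s * s - 4.0 * self.k21 * self.k10)
        alpha = 0.5 * (s + disc)
        beta = 0.5 * (s - disc)
        return alpha, beta


@dataclass(frozen=True)
class PBFTPKModel:
    """A finite-absorption-time model: absorption schedule + disposition."""

    schedule: AbsorptionSchedule
    disposition: Disposition

    def concentration(self, t):
        if isinstance(self.disposition, OneCompartmentDisposition):
            return concentration_one_compartment(self.schedule, self.disposition, t)
        return concentration_two_compartment(self.schedule, self.disposition, t)

    @property
    def auc_infinity(self) -> float:
        return auc_infinity_analytic(self)


@dataclass(frozen=True)
class BatemanModel:
    """Classical first-order absorption/elimination comparator.

    C(t) = scale * ka / (ka - kel) * (exp(-kel t) - exp(-ka t)), where scale
    houses F * D_po / V_d.  The degenerate case ka == kel is rejected.
    """

    ka: float
    kel: float
    scale: float

    def __post_init__(self) -> None:
        for name in ("ka", "kel", "scale"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be > 0, got {v}")
        if self.ka == self.kel:
            raise ValueError("degenerate Bateman form ka == kel is not supported")

    def concentration(self, t):
        return bateman_concentration(self, t)

    @property
    def tmax(self) -> float:
        return math.log(self.ka / self.kel) / (self.ka - self.kel)


def concentration_one_compartment(
    schedule: AbsorptionSchedule, disposition: OneCompartmentDisposition, t
):
    """Central concentration for piecewise-constant input with first-order loss.

    Built by superposing shifted constant-rate infusion solutions: each stage
    contributes (r/kel)(1 - exp(-kel (t - start)+)) switched off at its end.
    Continuous everywhere; C(0) = 0; pure exponential decay for t >= tau.
    """
    tt, scalar = _validated_times(t)
    k = disposition.kel
    out = np.zeros_like(tt)
    for rate, s, e in zip(schedule.rates, schedule.start_times, schedule.breakpoints):
        if rate == 0.0:
            continue
        out += (rate / k) * (
            np.exp(-k * np.maximum(tt - e, 0.0)) - np.exp(-k * np.maximum(tt - s, 0.0))
        )
    out = np.maximum(out, 0.0)
    return float(out[0]) if scalar else out


def concentration_two_compartment(
    schedule: AbsorptionSchedule, disposition: TwoCompartmentDisposition, t
):
    """Central concentration of the two-compartment system under staged input.

    The unit-impulse response of the central compartment is
    A exp(-alpha t) + B exp(-beta t) with A = (alpha - k21)/(alpha - beta),
    B = (k21 - beta)/(alpha - beta); each stage superposes the corresponding
    constant-infusion solution between its start and end times.
    """
    tt, scalar = _validated_times(t)
    alpha, beta = disposition.hybrid_constants
    k21 = disposition.k21
    span = alpha - beta
    if span <= 0:  # pragma: no cover - positivity guarantees alpha > beta
        raise ValueError("degenerate hybrid constants")
    a_coef = (alpha - k21) / span
    b_coef = (k21 - beta) / span

    def ramp(u: np.ndarray) -> np.ndarray:
        u = np.maximum(u, 0.0)
        return a_coef * (1.0 - np.exp(-alpha * u)) / alpha + b_coef * (
            1.0 - np.exp(-beta * u)
        ) / beta

    out = np.zeros_like(tt)
    for rate, s, e in zip(schedule.rates, schedule.start_times, schedule.breakpoints):
        if rate == 0.0:
            continue
        out += rate * (ramp(tt - s) - ramp(tt - e))
    out = np.maximum(out, 0.0)
    return float(out[0]) if scalar else out


def bateman_concentration(model: BatemanModel, t):
    """Evaluate the Bateman curve; C(0) = 0, single interior maximum."""
    tt, scalar = _validated_times(t)
    ka, kel, scale = model.ka, model.kel, model.scale
    out = scale * ka / (ka - kel) * (np.exp(-kel * tt) - np.exp(-ka * tt))
    out = np.maximum(out, 0.0)
    return float(out[0]) if scalar else out


def auc_infinity_analytic(model: PBFTPKModel) -> float:
    """Exact area under the curve to infinity.

    One compartment: (sum r_i tau_i) / kel.  Two compartments: the integral of
    the central impulse response is 1/k10, so AUC = (sum r_i tau_i) / k10.
    """
    total = model.schedule.total_amount
    disp = model.disposition
    if isinstance(disp, OneCompartmentDisposition):
        return total / disp.kel
    return total / disp.k10


def _slowest_rate_constant(model: PBFTPKModel) -> float:
    disp = model.disposition
    if isinstance(disp, OneCompartmentDisposition):
        return disp.kel
    return disp.hybrid_constants[1]


def cmax_tmax(model: PBFTPKModel) -> tuple[float, float]:
    """Peak concentration and its time for a PBFTPK model.

    For a one-compartment single-stage model the peak falls exactly at the end
    of absorption (concentration rises throughout input, decays after), so
    tmax = tau is returned exactly.  Otherwise a dense grid over
    [0, tau + 5 / slowest rate constant] is refined by bounded scalar
    minimization around the best grid point.
    """
    sched = model.schedule
    if isinstance(model.disposition, OneCompartmentDisposition) and sched.n_stages == 1:
        tau = sched.total_duration
        return float(model.concentration(tau)), tau

    horizon = sched.total_duration + 5.0 / _slowest_rate_constant(model)
    grid = np.linspace(0.0, horizon, 4097)
    vals = model.concentration(grid)
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda x: -model.concentration(x),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    # the peak often sits exactly at a stage breakpoint (a kink), so include
    # the breakpoints as explicit candidates alongside the refined point
    candidates = [float(res.x), float(grid[i])] + [float(b) for b in sched.breakpoints]
    best_t = max(candidates, key=lambda x: model.concentration(x))
    return float(model.concentration(best_t)), best_t
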