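"""Shared fixtures and independent numerical oracles.

The ODE oracle integrates the compartment equations directly with
scipy.integrate.solve_ivp (segment by segment, so the piecewise-constant
input never crosses an integration step discontinuously) and is kept fully
independent of the closed-form implementations it checks.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from pbftpk.models import (
    AbsorptionSchedule,
    InputStage,
    OneCompartmentDisposition,
    PBFTPKModel,
    TwoCompartmentDisposition,
)


def ode_concentration(model: PBFTPKModel, eval_times) -> np.ndarray:
    """Central concentration by direct numerical integration of the ODEs."""
    times = np.asarray(eval_times, dtype=float)
    sched, disp = model.schedule, model.disposition
    two = isinstance(disp, TwoCompartmentDisposition)

    edges = [0.0] + list(sched.breakpoints)
    horizon = float(max(times.max(), edges[-1]) + 1.0)
    if horizon > edges[-1]:
        edges = edges + [horizon]
    seg_rates = list(sched.rates) + [0.0]

    def rhs_factory(rate):
        if two:
            k12, k21, k10 = disp.k12, disp.k21, disp.k10

            def rhs(_t, y):
                c1, c2 = y
                return [rate - (k12 + k10) * c1 + k21 * c2, k12 * c1 - k21 * c2]

        else:
            kel = disp.kel

            def rhs(_t, y):
                return [rate - kel * y[0]]

        return rhs

    y = np.zeros(2 if two else 1)
    out = np.full_like(times, np.nan)
    out[times == 0.0] = 0.0
    for (lo, hi), rate in zip(zip(edges[:-1], edges[1:]), seg_rates):
        inside = (times > lo) & (times <= hi)
        t_eval = np.sort(times[inside])
        sol = solve_ivp(
            rhs_factory(rate),
            (lo, hi),
            y,
            method="DOP853",
            rtol=1e-11,
            atol=1e-15,
            t_eval=t_eval if t_eval.size else None,
            dense_output=False,
        )
        assert sol.success
        if t_eval.size:
            # map back to the original (already sorted-unique in our uses) order
            for tv, col in zip(sol.t, sol.y[0]):
                out[np.isclose(times, tv, rtol=0, atol=1e-12)] = col
        end = solve_ivp(
            rhs_factory(rate), (lo, hi), y, method="DOP853", rtol=1e-11, atol=1e-15
        )
        y = end.y[:, -1]
    assert np.all(np.isfinite(out))
    return out


def random_pbftpk(rng: np.random.Generator, two_compartment: bool) -> PBFTPKModel:
    """A randomized but physiologic model for property tests.

    Stage durations span the 0.7-6.3 h range typical of fitted oral schedules,
    and adjacent stages differ in rate by at least 1.5x — without a rate
    contrast the breakpoint between two stages is not identifiable even from
    noiseless data.
    """
    n_stages = int(rng.integers(1, 4))
    durations = rng.uniform(0.7, 6.3, size=n_stages)
    rates = [float(rng.uniform(0.1, 2.0))]
    for _ in range(n_stages - 1):
        factor = rng.uniform(1.5, 4.0)
        rates.append(rates[-1] * factor if rng.random() < 0.5 else rates[-1] / factor)
    stages = [InputStage(float(d), float(r)) for d, r in zip(durations, rates)]
    if two_compartment:
        disp = TwoCompartmentDisposition(
            k12=float(rng.uniform(0.05, 1.0)),
            k21=float(rng.uniform(0.05, 1.0)),
            k10=float(rng.uniform(0.05, 1.0)),
        )
    else:
        disp = OneCompartmentDisposition(kel=float(rng.uniform(0.05, 1.5)))
    return PBFTPKModel(AbsorptionSchedule(stages), disp)


def slowest_constant(model: PBFTPKModel) -> float:
    disp = model.disposition
    if isinstance(disp, OneCompartmentDisposition):
        return disp.kel
    return disp.hybrid_constants[1]


@pytest.fixture
def unit_one_stage_model() -> PBFTPKModel:
    """Single stage r=1 conc/h, tau=1 h, kel=1 /h — the canonical unit case."""
    return PBFTPKModel(
        AbsorptionSchedule([InputStage(1.0, 1.0)]), OneCompartmentDisposition(kel=1.0)
    )


@pytest.fixture
def theodur_schedule() -> AbsorptionSchedule:
    """Three-stage extended-release schedule (published fitted values)."""
    return AbsorptionSchedule(
        [InputStage(4.2, 0.0009), InputStage(3.2, 0.0024), InputStage(4.2, 0.0016)]
    )
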