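"""Fraction-absorbed versus time curves from fitted absorption schedules.

Because every stage delivers drug at a constant rate, the cumulative amount
absorbed is piecewise linear in time and reaches the total exactly at the
finite absorption time tau — by construction the curve attains 1 (no
asymptote), in contrast to deconvolution-style reconstructions that plateau
below 1 on real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import AbsorptionSchedule

__all__ = ["FractionAbsorbedCurve", "fraction_absorbed_curve"]


@dataclass(frozen=True)
class FractionAbsorbedCurve:
    """FA(t): nondecreasing, 0 at t = 0, exactly 1 for all t >= tau_total."""

    times: np.ndarray
    fractions: np.ndarray
    tau_total: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "fractions", np.asarray(self.fractions, dtype=float))
        if len(self.times) != len(self.fractions):
            raise ValueError("times and fractions must have equal length")


def fraction_absorbed_curve(
    schedule: AbsorptionSchedule, times
) -> FractionAbsorbedCurve:
    """Evaluate the fraction-absorbed curve of a staged zero-order schedule.

    FA(t) = sum_i rate_i * overlap(t, stage i) / sum_i rate_i * tau_i —
    piecewise linear with slope proportional to the stage rate, slope changes
    exactly at the stage breakpoints, and FA = 1 exactly from tau onward.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ValueError("times must be 1-D")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    total = schedule.total_amount
    if total <= 0:
        raise ValueError("schedule absorbs zero total amount; fraction undefined")
    tau = schedule.total_duration
    absorbed = np.zeros_like(t)
    for rate, start, dur in zip(schedule.rates, schedule.start_times, schedule.durations):
        absorbed += rate * np.clip(t - start, 0.0, dur)
    fa = absorbed / total
    fa = np.where(t >= tau, 1.0, np.minimum(fa, 1.0))
    return FractionAbsorbedCurve(times=t, fractions=fa, tau_total=tau)
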