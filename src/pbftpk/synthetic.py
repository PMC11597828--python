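"""Synthetic oral concentration-time profiles with known ground truth.

The templates emulate the kinds of single-dose oral profiles analysed in the
finite-absorption-time literature: 1-3 successive zero-order input stages,
one- or two-compartment disposition, sparse clinical sampling (8-15 points
over 8-48 h), and proportional + additive measurement noise standing in for
assay and figure-digitization error.

Absorption schedules (stage durations and rates) follow published fitted
values for the named drugs/formulations.  Disposition rate constants and
sampling schedules are NOT published alongside them; the values here are
synthetic fixture choices picked once for physiological plausibility (see
docs/methods.md) — only the absorption parameters carry over.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .models import (
    AbsorptionSchedule,
    ConcentrationTimeSeries,
    InputStage,
    OneCompartmentDisposition,
    PBFTPKModel,
    TwoCompartmentDisposition,
)

__all__ = ["NoiseModel", "StudyTemplate", "generate_profile", "study_fixture", "template_names"]


@dataclass(frozen=True)
class NoiseModel:
    """Proportional + additive Gaussian measurement noise with an LOQ.

    Observed = max(0, C_true * (1 + eps_p) + eps_a), eps_p ~ N(0, cv^2),
    eps_a ~ N(0, sd^2).  Values below `loq` are dropped (default) or zeroed.
    Identical seed gives identical draws.
    """

    proportional_cv: float = 0.05
    additive_sd: float = 0.0
    loq: float = 0.0
    drop_below_loq: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.proportional_cv < 0 or self.additive_sd < 0 or self.loq < 0:
            raise ValueError("noise parameters must be nonnegative")

    @classmethod
    def noiseless(cls, seed: int = 0) -> "NoiseModel":
        return cls(proportional_cv=0.0, additive_sd=0.0, loq=0.0, seed=seed)


@dataclass(frozen=True)
class StudyTemplate:
    name: str
    model: PBFTPKModel
    sampling_times: tuple[float, ...]
    unit_label: str


def _one_comp(durations, rates, kel) -> PBFTPKModel:
    return PBFTPKModel(
        AbsorptionSchedule([InputStage(d, r) for d, r in zip(durations, rates)]),
        OneCompartmentDisposition(kel=kel),
    )


def _two_comp(durations, rates, k12, k21, k10) -> PBFTPKModel:
    return PBFTPKModel(
        AbsorptionSchedule([InputStage(d, r) for d, r in zip(durations, rates)]),
        TwoCompartmentDisposition(k12=k12, k21=k21, k10=k10),
    )


# Absorption schedules from published fits; disposition constants and sampling
# grids are synthetic fixture choices (rationale in docs/methods.md).
_TEMPLATES: dict[str, StudyTemplate] = {
    "ketoprofen_like": StudyTemplate(
        name="ketoprofen_like",
        model=_one_comp([0.75], [0.031], kel=0.64),
        sampling_times=(0.17, 0.33, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0),
        unit_label="mg/mL",
    ),
    "amlodipine_like": StudyTemplate(
        name="amlodipine_like",
        model=_two_comp([2.1, 5.3], [1.16, 0.80], k12=0.1, k21=0.05, k10=0.05),
        sampling_times=(1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 10.0, 12.0, 24.0, 36.0, 48.0),
        unit_label="ng/mL",
    ),
    "theophylline_ir_like": StudyTemplate(
        name="theophylline_ir_like",
        model=_one_comp([1.2, 1.3], [0.0068, 0.0011], kel=0.115),
        sampling_times=(0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 6.0, 8.0, 10.0, 12.0),
        unit_label="mg/mL",
    ),
    "theotrim_like": StudyTemplate(
        name="theotrim_like",
        model=_one_comp([0.72, 6.28], [0.0018, 0.0007], kel=0.07),
        sampling_times=(0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 10.0, 12.0, 16.0, 24.0),
        unit_label="mg/mL",
    ),
    "theodur_like": StudyTemplate(
        name="theodur_like",
        model=_one_comp([4.2, 3.2, 4.2], [0.0009, 0.0024, 0.0016], kel=0.0866),
        sampling_times=(1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 12.0, 14.0, 16.0, 20.0, 24.0),
        unit_label="mg/mL",
    ),
    "levonorgestrel_like": StudyTemplate(
        name="levonorgestrel_like",
        model=_two_comp([1.09], [8.3], k12=0.35, k21=0.12, k10=0.25),
        sampling_times=(0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0, 36.0, 48.0),
        unit_label="ng/mL",
    ),
}


def template_names() -> list[str]:
    return sorted(_TEMPLATES)


def generate_profile(
    model: PBFTPKModel,
    sampling_times,
    noise: Optional[NoiseModel] = None,
    unit_label: str = "ng/mL",
    label: str = "simulated",
) -> ConcentrationTimeSeries:
    """Simulate an observed profile: forward model + measurement noise + LOQ.

    With zero noise the output equals the forward model exactly at every
    sampling time; with a fixed seed the draws are reproducible.
    """
    times = np.asarray(sampling_times, dtype=float)
    if times.size == 0:
        raise ValueError("sampling schedule must contain at least one time")
    if np.any(np.diff(times) <= 0):
        raise ValueError("sampling times must be strictly increasing")
    noise = noise if noise is not None else NoiseModel.noiseless()
    c_true = np.atleast_1d(model.concentration(times))
    rng = np.random.default_rng(noise.seed)
    eps_p = rng.normal(0.0, noise.proportional_cv, size=c_true.shape)
    eps_a = rng.normal(0.0, noise.additive_sd, size=c_true.shape)
    obs = np.maximum(0.0, c_true * (1.0 + eps_p) + eps_a)
    if noise.loq > 0:
        below = obs < noise.loq
        if noise.drop_below_loq:
            times, obs = times[~below], obs[~below]
        else:
            obs = np.where(below, 0.0, obs)
    return ConcentrationTimeSeries(
        times=times, concentrations=obs, unit_label=unit_label, label=label
    )


def study_fixture(
    name: str, noise: Optional[NoiseModel] = None
) -> tuple[ConcentrationTimeSeries, PBFTPKModel]:
    """Return a noisy series from a named study template plus its ground truth."""
    if name not in _TEMPLATES:
        raise ValueError(
            f"unknown template {name!r}; valid names: {', '.join(template_names())}"
        )
    tpl = _TEMPLATES[name]
    series = generate_profile(
        tpl.model, tpl.sampling_times, noise, unit_label=tpl.unit_label, label=tpl.name
    )
    return series, tpl.model
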