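"""Nonlinear least-squares estimation of finite-absorption-time PK models.

Parameters are estimated by unweighted least squares on the concentration
scale.  All parameters are positive by construction: the optimizer works on
log-transformed values, which also keeps stage breakpoints ordered since
durations are fitted as positive increments.  Estimation uses seeded
multistart (a data-driven base guess plus jittered restarts) so that results
are deterministic given a seed.

Standard errors come from the Jacobian-based covariance at the optimum,
scaled by SSR / (n_obs - n_params), and are mapped back to the natural scale
with the delta method.

Model comparison uses the small-sample-corrected information criterion (AICc)
computed from the Gaussian SSR.  SSRs are floored at n * (1e-8 * Cmax)^2 when
forming the criterion so that models fitting noiseless data to machine
precision tie, and the parameter-count penalty breaks the tie toward the
smaller model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

from .models import (
    AbsorptionSchedule,
    BatemanModel,
    ConcentrationTimeSeries,
    InputStage,
    OneCompartmentDisposition,
    PBFTPKModel,
    TwoCompartmentDisposition,
)

__all__ = [
    "FitResult",
    "ModelComparison",
    "ComparisonEntry",
    "fit_pbftpk",
    "fit_bateman",
    "compare_models",
    "aicc_from_ssr",
]

ONE_COMPARTMENT = "one_compartment"
TWO_COMPARTMENT = "two_compartment"

_N_RESTARTS = 10  # multistart budget for small models
_N_RESTARTS_LARGE = 24  # models with > 6 parameters need wider exploration
_JITTER_SD = 0.6  # log-space sd of restart jitter
_MAX_NFEV = 200


def _restart_budget(n_params: int) -> int:
    return _N_RESTARTS if n_params <= 6 else _N_RESTARTS_LARGE


@dataclass
class FitResult:
    """Least-squares estimates with uncertainties for one fitted model.

    `estimates` and `standard_errors` are keyed by parameter name
    (tau1.., rate1.., kel or k12/k21/k10; or ka/kel/scale for Bateman).
    `residuals` are observed minus fitted.
    """

    model_spec: str
    param_names: list[str]
    estimates: dict[str, float]
    standard_errors: dict[str, float]
    covariance: np.ndarray
    correlation: np.ndarray
    residuals: np.ndarray
    ssr: float
    converged: bool
    n_obs: int
    n_params: int
    message: str = ""

    def to_model(self) -> Union[PBFTPKModel, BatemanModel]:
        """Rebuild the fitted model object from the estimates."""
        e = self.estimates
        if self.model_spec == "bateman":
            return BatemanModel(ka=e["ka"], kel=e["kel"], scale=e["scale"])
        disp_type, n_stages = _parse_spec(self.model_spec)
        stages = [
            InputStage(duration=e[f"tau{i + 1}"], rate=e[f"rate{i + 1}"])
            for i in range(n_stages)
        ]
        if disp_type == ONE_COMPARTMENT:
            disp = OneCompartmentDisposition(kel=e["kel"])
        else:
            disp = TwoCompartmentDisposition(k12=e["k12"], k21=e["k21"], k10=e["k10"])
        return PBFTPKModel(AbsorptionSchedule(stages), disp)

    @property
    def total_duration(self) -> Optional[float]:
        """Fitted finite absorption time (None for the Bateman comparator)."""
        if self.model_spec == "bateman":
            return None
        _, n = _parse_spec(self.model_spec)
        return float(sum(self.estimates[f"tau{i + 1}"] for i in range(n)))


@dataclass
class ComparisonEntry:
    model_spec: str
    ssr: Optional[float]
    n_params: Optional[int]
    information_criterion: Optional[float]
    converged: bool
    error: str = ""
    fit: Optional[FitResult] = field(default=None, repr=False)


@dataclass
class ModelComparison:
    """Fits of several candidate models to one series, ranked by AICc."""

    entries: list[ComparisonEntry]
    ranking: list[str]

    @property
    def best(self) -> ComparisonEntry:
        if not self.ranking:
            raise ValueError("no candidate model could be fitted")
        by_spec = {e.model_spec: e for e in self.entries}
        return by_spec[self.ranking[0]]


def _parse_spec(spec: str) -> tuple[str, int]:
    """Parse 'one_compartment:2' style model descriptors."""
    disp, _, n = spec.partition(":")
    if disp not in (ONE_COMPARTMENT, TWO_COMPARTMENT) or not n:
        raise ValueError(
            f"bad model spec {spec!r}: expected 'bateman' or "
            f"'{ONE_COMPARTMENT}:<n>' / '{TWO_COMPARTMENT}:<n>'"
        )
    n_stages = int(n)
    if n_stages < 1:
        raise ValueError("n_stages must be >= 1")
    return disp, n_stages


def _param_names(disp_type: str, n_stages: int) -> list[str]:
    names = [f"tau{i + 1}" for i in range(n_stages)]
    names += [f"rate{i + 1}" for i in range(n_stages)]
    if disp_type == ONE_COMPARTMENT:
        names.append("kel")
    else:
        names += ["k12", "k21", "k10"]
    return names


def _build_pbftpk(theta: np.ndarray, disp_type: str, n_stages: int) -> PBFTPKModel:
    taus = theta[:n_stages]
    rates = theta[n_stages : 2 * n_stages]
    stages = [InputStage(duration=float(d), rate=float(r)) for d, r in zip(taus, rates)]
    if disp_type == ONE_COMPARTMENT:
        disp = OneCompartmentDisposition(kel=float(theta[2 * n_stages]))
    else:
        k12, k21, k10 = theta[2 * n_stages : 2 * n_stages + 3]
        disp = TwoCompartmentDisposition(k12=float(k12), k21=float(k21), k10=float(k10))
    return PBFTPKModel(AbsorptionSchedule(stages), disp)


def _terminal_slope_guess(times: np.ndarray, conc: np.ndarray) -> float:
    """Crude kel (or beta) from a log-linear fit on the last third of points."""
    m = max(3, len(times) // 3)
    t_tail, c_tail = times[-m:], conc[-m:]
    pos = c_tail > 0
    if pos.sum() >= 2 and len(np.unique(t_tail[pos])) >= 2:
        res = linregress(t_tail[pos], np.log(c_tail[pos]))
        if res.slope < 0:
            return float(-res.slope)
    return 1.0 / max(times[-1], 1e-6)


def _base_guess_pbftpk(
    times: np.ndarray, conc: np.ndarray, disp_type: str, n_stages: int
) -> np.ndarray:
    i_peak = int(np.argmax(conc))
    t_peak = times[i_peak] if times[i_peak] > 0 else times[min(i_peak + 1, len(times) - 1)]
    t_peak = max(t_peak, times[-1] * 0.05, 1e-3)
    # keep at least one observation beyond the initial total duration
    total0 = min(1.2 * t_peak, 0.9 * times[-1])
    taus0 = np.full(n_stages, total0 / n_stages)
    rate0 = max(conc.max(), 1e-12) / t_peak  # rising-limb slope
    rates0 = np.full(n_stages, rate0)
    k0 = _terminal_slope_guess(times, conc)
    if disp_type == ONE_COMPARTMENT:
        disp0 = np.array([k0])
    else:
        # (2b, 2b, 3b) has slow hybrid root exactly b — anchors the terminal slope
        disp0 = np.array([2.0 * k0, 2.0 * k0, 3.0 * k0])
    return np.concatenate([taus0, rates0, disp0])


def _covariance_natural_scale(
    jac_log: np.ndarray, theta: np.ndarray, ssr: float, n_obs: int, n_params: int
) -> np.ndarray:
    """Delta-method covariance: optimizer works in log space, report natural."""
    dof = max(n_obs - n_params, 1)
    s2 = ssr / dof
    jtj = jac_log.T @ jac_log
    cov_log = s2 * np.linalg.pinv(jtj)
    d = np.diag(theta)  # d theta / d log-theta = theta
    return d @ cov_log @ d


def _correlation(cov: np.ndarray) -> np.ndarray:
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(se, se)
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def _run_multistart(
    residual_fn, phi0: np.ndarray, seed: int, n_durations: int = 0
):
    """LM from the base guess plus restarts; best SSR wins, ties to first found.

    The first restarts rescale the guessed stage durations (the base guess
    anchors the total duration near the observed peak, which can be far off
    for multi-stage profiles); the remainder are random log-space jitters.
    """
    rng = np.random.default_rng(seed)
    structured: list[np.ndarray] = []
    for scale in (0.6, 1.5, 2.2):
        phi = phi0.copy()
        phi[:n_durations] += math.log(scale)
        structured.append(phi)
    best = None
    for start in range(_restart_budget(len(phi0))):
        if start == 0:
            phi = phi0
        elif start <= len(structured):
            phi = structured[start - 1]
        else:
            phi = phi0 + rng.normal(0.0, _JITTER_SD, size=phi0.shape)
        try:
            res = least_squares(
                residual_fn,
                phi,
                method="lm",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=_MAX_NFEV * (len(phi0) + 1),
            )
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        if best is None or res.cost < best.cost * (1.0 - 1e-12):
            best = res
    return best


def _finish_fit(
    spec: str,
    names: list[str],
    best,
    observed: np.ndarray,
    n_obs: int,
) -> FitResult:
    n_params = len(names)
    theta = np.exp(best.x)
    fitted_minus_obs = best.fun  # residual_fn returns predicted - observed
    residuals = -fitted_minus_obs
    ssr = float(np.sum(fitted_minus_obs**2))
    cov = _covariance_natural_scale(best.jac, theta, ssr, n_obs, n_params)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return FitResult(
        model_spec=spec,
        param_names=list(names),
        estimates={k: float(v) for k, v in zip(names, theta)},
        standard_errors={k: float(v) for k, v in zip(names, se)},
        covariance=cov,
        correlation=_correlation(cov),
        residuals=residuals,
        ssr=ssr,
        converged=bool(best.success),
        n_obs=n_obs,
        n_params=n_params,
        message=str(best.message),
    )


def fit_pbftpk(
    series: ConcentrationTimeSeries,
    disposition_type: str = ONE_COMPARTMENT,
    n_stages: int = 1,
    initial_guess: Optional[dict[str, float]] = None,
    seed: int = 0,
) -> FitResult:
    """Fit an n-stage PBFTPK model to an oral concentration-time series.

    Parameters
    ----------
    series : ConcentrationTimeSeries
        Observed profile; needs at least n_params + 2 points and nonzero signal.
    disposition_type : {"one_compartment", "two_compartment"}
    n_stages : int
        Number of successive zero-order input stages (1-3 typical).
    initial_guess : dict, optional
        Named starting values (tau1.., rate1.., kel or k12/k21/k10);
        unspecified values fall back to the data-driven defaults.
    seed : int
        Seeds the jittered multistart; identical seed gives identical results.
    """
    if disposition_type not in (ONE_COMPARTMENT, TWO_COMPARTMENT):
        raise ValueError(f"unknown disposition_type {disposition_type!r}")
    names = _param_names(disposition_type, n_stages)
    n_params = len(names)
    n_obs = len(series)
    if n_obs < n_params + 2:
        raise ValueError(
            f"need at least {n_params + 2} observations to fit {n_params} "
            f"parameters, got {n_obs}"
        )
    times, conc = series.times, series.concentrations
    if conc.max() <= 0:
        raise ValueError("series has no signal (all concentrations are zero)")

    theta0 = _base_guess_pbftpk(times, conc, disposition_type, n_stages)
    if initial_guess:
        for i, name in enumerate(names):
            if name in initial_guess:
                v = float(initial_guess[name])
                if v <= 0:
                    raise ValueError(f"initial guess for {name} must be > 0, got {v}")
                theta0[i] = v
        total0 = float(np.sum(theta0[:n_stages]))
        if not np.any(times > total0):
            raise ValueError(
                "no observation after the initial-guess total duration "
                f"({total0:.3g} h); cannot anchor the elimination phase"
            )

    def residual_fn(phi: np.ndarray) -> np.ndarray:
        model = _build_pbftpk(np.exp(np.clip(phi, -50.0, 50.0)), disposition_type, n_stages)
        with np.errstate(over="ignore", invalid="ignore"):
            pred = model.concentration(times)
        pred = np.nan_to_num(pred, nan=1e30, posinf=1e30)
        return pred - conc

    best = _run_multistart(residual_fn, np.log(theta0), seed, n_durations=n_stages)
    if best is None:
        raise RuntimeError(
            f"fit of {disposition_type}:{n_stages} failed to produce any finite "
            "solution in the multistart budget"
        )
    spec = f"{disposition_type}:{n_stages}"
    return _finish_fit(spec, names, best, conc, n_obs)


def fit_bateman(
    series: ConcentrationTimeSeries,
    initial_guess: Optional[dict[str, float]] = None,
    seed: int = 0,
) -> FitResult:
    """Fit the Bateman comparator (first-order absorption) to a series.

    The curve is invariant under swapping ka and kel (with scale rescaled), so
    the result is canonicalized to ka > kel.
    """
    n_obs = len(series)
    if n_obs < 5:
        raise ValueError(f"Bateman fit needs at least 5 observations, got {n_obs}")
    times, conc = series.times, series.concentrations
    if conc.max() <= 0:
        raise ValueError("series has no signal (all concentrations are zero)")

    kel0 = _terminal_slope_guess(times, conc)
    i_peak = int(np.argmax(conc))
    t_peak = max(times[i_peak], times[-1] * 0.05, 1e-3)
    ka0 = 2.0 / t_peak + 2.0 * kel0
    scale0 = max(conc.max(), 1e-12) * 1.5
    theta0 = np.array([ka0, kel0, scale0])
    names = ["ka", "kel", "scale"]
    if initial_guess:
        for i, name in enumerate(names):
            if name in initial_guess:
                theta0[i] = float(initial_guess[name])

    def residual_fn(phi: np.ndarray) -> np.ndarray:
        ka, kel, scale = np.exp(np.clip(phi, -50.0, 50.0))
        if abs(ka - kel) < 1e-12 * max(ka, kel):
            kel *= 1.0 + 1e-9  # keep away from the removable singularity
        with np.errstate(over="ignore", invalid="ignore"):
            pred = scale * ka / (ka - kel) * (np.exp(-kel * times) - np.exp(-ka * times))
        pred = np.nan_to_num(pred, nan=1e30, posinf=1e30, neginf=-1e30)
        return pred - conc

    best = _run_multistart(residual_fn, np.log(theta0), seed)
    if best is None:
        raise RuntimeError("Bateman fit failed to produce any finite solution")
    result = _finish_fit("bateman", names, best, conc, n_obs)
    e = result.estimates
    if e["ka"] < e["kel"]:  # flip-flop: swap to canonical ka > kel
        ka, kel, scale = e["ka"], e["kel"], e["scale"]
        result.estimates = {"ka": kel, "kel": ka, "scale": scale * ka / kel}
        se = result.standard_errors
        result.standard_errors = {"ka": se["kel"], "kel": se["ka"], "scale": se["scale"]}
        perm = [1, 0, 2]
        result.covariance = result.covariance[np.ix_(perm, perm)]
        result.correlation = result.correlation[np.ix_(perm, perm)]
    return result


def aicc_from_ssr(ssr: float, n_obs: int, n_params: int) -> float:
    """Small-sample-corrected information criterion from a Gaussian SSR."""
    if n_obs - n_params - 1 <= 0:
        return math.inf
    return (
        n_obs * math.log(ssr / n_obs)
        + 2 * n_params
        + 2 * n_params * (n_params + 1) / (n_obs - n_params - 1)
    )


def _fit_by_spec(series, spec: str, seed: int) -> FitResult:
    if spec == "bateman":
        return fit_bateman(series, seed=seed)
    disp_type, n_stages = _parse_spec(spec)
    return fit_pbftpk(series, disp_type, n_stages, seed=seed)


def compare_models(
    series: ConcentrationTimeSeries,
    candidates: Sequence[str],
    seed: int = 0,
) -> ModelComparison:
    """Fit each candidate model and rank by AICc (ties toward fewer parameters).

    Candidates are 'bateman' or '<disposition>:<n_stages>' strings.  A
    candidate that fails to fit is recorded with its error, not dropped.
    """
    if not candidates:
        raise ValueError("need at least one candidate model")
    cmax = float(series.concentrations.max()) if len(series) else 0.0
    floor = len(series) * (1e-8 * cmax) ** 2
    entries: list[ComparisonEntry] = []
    for spec in candidates:
        try:
            fit = _fit_by_spec(series, spec, seed)
        except Exception as exc:
            entries.append(
                ComparisonEntry(spec, None, None, None, converged=False, error=str(exc))
            )
            continue
        ssr_eff = max(fit.ssr, floor)
        ic = aicc_from_ssr(ssr_eff, fit.n_obs, fit.n_params)
        entries.append(
            ComparisonEntry(spec, fit.ssr, fit.n_params, ic, fit.converged, fit=fit)
        )
    ok = [e for e in entries if e.fit is not None and math.isfinite(e.information_criterion)]
    ok.sort(key=lambda e: (e.information_criterion, e.n_params))
    return ModelComparison(entries=entries, ranking=[e.model_spec for e in ok])
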