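# Methods

## The model

`pbftpk` analyses single-dose oral concentration–time profiles under the
finite-absorption-time premise: gastrointestinal absorption is a sequence of
one to three successive **zero-order** (constant-rate) input stages that
terminates at a finite time τ (the sum of the stage durations), rather than a
first-order process running forever. Physiologically, the rapid portal-vein
blood flow keeps sink conditions at the gut wall, so the transfer rate is set
by the luminal supply, not by a concentration gradient — hence constant-rate
input per stage, with rate changes when the dose moves to a new absorption
environment (e.g. small intestine → colon).

The forward model is a linear compartment system with piecewise-constant
input:

* **One-compartment disposition.** Each stage with rate `r` (concentration
  per hour, i.e. amount per central volume per hour) starting at `s` and
  ending at `e` contributes

  `C(t) += (r/kel) * [exp(-kel·(t-e)₊) - exp(-kel·(t-s)₊)]`

  (a started infusion minus a stopped one). The sum is continuous, zero at
  t = 0, and decays as a single exponential after τ.

* **Two-compartment disposition.** Micro-constants `k12` (central →
  peripheral), `k21` (back), `k10` (elimination). The central
  unit-impulse response is `A·e^{-αt} + B·e^{-βt}` with hybrid constants
  α > β > 0 the roots of `s² + (k12+k21+k10)s + k21·k10 = 0`,
  `A = (α-k21)/(α-β)`, `B = (k21-β)/(α-β)`; each stage superposes the
  corresponding constant-infusion solution between its start and end.

Rates are carried per central-compartment volume throughout, so the product
rate × duration of a stage is the composite `Fᵢ·D/V` on the concentration
scale and no dose or volume of distribution ever appears explicitly. The
analytic AUC to infinity is `Σ rᵢτᵢ / kel` (one compartment) or
`Σ rᵢτᵢ / k10` (two compartments).

The classical **Bateman** curve (first-order absorption,
`C = scale·ka/(ka-kel)·(e^{-kel·t} - e^{-ka·t})`) is included purely as a
comparator; its degenerate case `ka = kel` is rejected rather than given the
`t·e^{-kt}` limit form, since it is never needed in this context.

## Fitting

Unweighted least squares on the concentration scale. All parameters are
positive physical quantities, so the optimizer (Levenberg–Marquardt via
`scipy.optimize.least_squares`) works on log-transformed values; stage
durations are fitted as positive increments, which keeps breakpoints ordered
without constraint machinery. Initialization is data-driven: the terminal
slope from a log-linear fit on the last third of points, breakpoints from an
even split of `[0, 1.2·t_peak]`, stage rates from the rising-limb slope
`Cmax/t_peak`; for two-compartment fits the disposition constants start at
`(2β̂, 2β̂, 3β̂)`, a triple whose slow hybrid root is exactly the observed
terminal slope β̂.

Multistart: the base guess, three structured restarts that rescale the
guessed stage durations by 0.6/1.5/2.2 (the peak-anchored guess is
systematically short for multi-stage profiles), and seeded log-normal jitter
(sd 0.6) for the rest. The budget is 10 starts for models with ≤ 6 parameters
and 24 for larger ones — noiseless 7–9-parameter scenarios occasionally need
the wider exploration to escape local minima. Best SSR wins, ties to the
first found; identical seeds give identical results. Convergence tolerances
are `xtol = ftol = gtol = 1e-12` with 200·(p+1) function evaluations per
start.

Standard errors come from the Jacobian-based covariance at the optimum
scaled by `SSR/(n-p)`, mapped from log to natural scale by the delta method;
correlations follow from the covariance. Bateman fits are reported in the
canonical flip-flop orientation `ka > kel` (the curve is invariant under
swapping `ka` and `kel` with `scale·ka` held fixed).

Model comparison ranks candidates by the small-sample-corrected information
criterion `AICc = n·ln(SSR/n) + 2p + 2p(p+1)/(n-p-1)`. The SSR entering the
criterion is floored at `n·(1e-8·Cmax)²`: models that fit noiseless data to
machine precision then tie, and the parameter penalty resolves the tie
toward the smaller model — otherwise numerically-zero SSRs would be ranked
by floating-point noise. Candidates that fail to fit are recorded with their
error, never silently dropped. Below-quantification values are dropped by
the generator by default (configurable to zero-fill), never imputed.

## Bioavailability from oral data alone

* **One input stage** (one-compartment): `F = kel·τ / (e^{kel·τ} - 1)`;
  strictly decreasing in `kel·τ`, → 1 as absorption becomes instantaneous.
* **Two input stages**: with stage composites `aᵢ = rᵢτᵢ`,
  `F = (a₁+a₂)·kel / [(a₁/τ₁)(e^{kelτ₁}-1) + (a₂/τ₂)e^{kelτ₁}(e^{kelτ₂}-1)]`.
  With `a₂ = 0` this reduces exactly to the one-stage form at τ₁; with equal
  stage rates, to the one-stage form at τ₁+τ₂.
* **Semi-noncompartmental**: `F* = (AUC_oral / AUC_hyp.iv)^exponent`. The
  hypothetical IV bolus is built by ordinary least squares of
  ln C on t over all points with `t > τ` (taken literally — no r²-maximizing
  subset selection), back-extrapolated to t = 0; `AUC_hyp.iv = C₀/k̂el`.
  `AUC_oral` is the linear trapezoid over the observed range plus the tail
  `C_last/k̂el`, using the same fitted terminal slope so the estimator is
  self-contained in oral data. On data exactly consistent with the staged
  model, the exponent-1 ratio coincides with the closed forms above (the
  back-extrapolated intercept is `Σ rᵢ(e^{kel·eᵢ} - e^{kel·sᵢ})/kel`, which
  is the closed-form denominator over kel).

The exponent defaults to ½ and is an explicit parameter: the square-root
form and the plain ratio answer slightly different questions and published
usage is not uniform, so both are one call away. F* equals F only in the
absence of a first-pass effect; nothing here models first-pass extraction.

The **fraction-absorbed curve** is computed from fitted parameters only:
`FA(t) = Σ rᵢ·overlap(t, stage i) / Σ rᵢτᵢ`, piecewise linear with slope
proportional to the stage rate, reaching 1 *exactly* at τ (enforced exactly
in code for `t ≥ τ`). This is deliberately not a Wagner–Nelson-style
reconstruction from the observed data.

## Synthetic data and what it does (not) show

Templates named `*_like` reproduce published fitted absorption schedules
(stage durations and rates) for: ketoprofen (1 stage, 0.75 h, 0.031
mg·mL⁻¹·h⁻¹), amlodipine (2.1 + 5.3 h), immediate-release theophylline
(1.2 + 1.3 h), the extended-release theophylline formulations Theotrim
(0.72 + 6.28 h) and Theodur (4.2 + 3.2 + 4.2 h), and levonorgestrel
(reference, 1.09 h, two-compartment). The disposition constants are **not**
published with those schedules; the package adopts plausible fixture values,
chosen once: kel = 0.64 /h (ketoprofen, a short ~1 h half-life NSAID),
0.115 /h and 0.07 /h (theophylline IR / Theotrim, 6–10 h half-lives),
0.0866 /h (Theodur, the textbook 8 h theophylline half-life), and micro
constants (0.1, 0.05, 0.05) /h for amlodipine and (0.35, 0.12, 0.25) /h for
levonorgestrel. Sampling grids are typical clinical designs (dense early,
sparse late; 11–15 points over 8–48 h). Noise is proportional (default CV
5%) plus optional additive, with an optional limit of quantification below
which points are dropped or zeroed.

Because the inputs are generated by the same model family that is fitted,
passing round-trip tests demonstrates the correctness and stability of the
machinery — not that real profiles follow staged zero-order input, and not
that the fixture disposition constants are the true ones for those drugs.
The noisy-recovery study (5% CV, 100 replicates per template) shows median
relative errors of the total absorption duration of 2–5% for most templates;
the immediate-release theophylline template is the documented exception
(~13%): its second stage carries only ~15% of the amount at a 6:1 rate
contrast, so the second breakpoint is weakly identified at this noise level
— restarting from the true parameters does not reduce the SSR, i.e. the
dispersion is a property of the least-squares estimate itself, not of the
optimizer.

## Numerical choices and edge cases

* Time is hours, t = 0 is dose administration; negative times are rejected.
* Published rate tables headed "mg h/mL" are read as mg·mL⁻¹·h⁻¹
  (concentration per hour): rate × duration must land on the concentration
  scale for the closed-form F expressions to be dimensionless.
* Simulator outputs are clipped at 0 (they are analytically nonnegative;
  the clip guards rounding at C ≈ 0).
* `cmax_tmax` returns τ exactly for one-compartment single-stage models
  (the peak provably sits at the end of absorption); otherwise a 4097-point
  grid over `[0, τ + 5/k_slow]` refined by bounded scalar minimization, with
  stage breakpoints always included as candidates since kinks are the
  typical peak location.
* Terminal-phase fits require ≥ 3 positive points strictly beyond τ;
  nonpositive tail points are excluded with a warning.
* Log-parameter vectors are clipped to ±50 during optimization and
  non-finite model evaluations are mapped to large residuals, so wandering
  restarts fail gracefully instead of poisoning the fit.
* Series with all-zero concentrations, too few points for the requested
  parameter count, or non-increasing times are rejected with messages naming
  the offending quantity.

## Known limitations

* Absorption models other than staged zero-order input (first-order,
  transit-compartment, saturable), enterohepatic recirculation, and multiple
  dosing are out of scope.
* No population (mixed-effects) estimation, no weighted or robust
  regression, no bootstrap intervals.
* True absolute bioavailability from a paired IV arm is not implemented;
  F* from the hypothetical-bolus construction inherits any first-pass
  effect and any error in τ (a τ set too early contaminates the terminal
  fit with absorption-phase points; too late discards information).
* The AUC tail `C_last/k̂el` assumes mono-exponential decay beyond the last
  sample; for two-compartment profiles sampled before the distribution
  phase has resolved, the fitted "terminal" slope mixes α and β.
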