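# pbftpk

Finite-absorption-time pharmacokinetic analysis of single-dose oral
concentration–time profiles.

Classical oral PK describes absorption with a first-order rate constant
`ka`, which implies that absorption continues forever. Physiologically it
does not: gastrointestinal transit bounds it, and the rapid portal-vein
blood flow maintains sink conditions at the gut wall, making the transfer
rate constant while a dose region lasts. `pbftpk` implements the resulting
model family — **1–3 successive zero-order input stages of durations τᵢ and
rates rᵢ feeding one- or two-compartment disposition** — together with
everything needed to use it on real or simulated profiles:

* closed-form forward simulation (continuous, exact exponential tail after
  the finite absorption time τ = Στᵢ), plus the classical Bateman curve
  `C = scale·ka/(ka−kel)·(e^{−kel·t} − e^{−ka·t})` as a comparator;
* nonlinear least-squares fitting with positivity by construction, seeded
  multistart, Jacobian-based standard errors/correlations, and AICc model
  comparison across stage counts and dispositions;
* bioavailable-fraction estimation **from oral data alone**:

  one stage: `F = kel·τ / (e^{kel·τ} − 1)`

  two stages (stage composites `aᵢ = rᵢτᵢ`):
  `F = (a₁+a₂)·kel / [(a₁/τ₁)(e^{kelτ₁}−1) + (a₂/τ₂)·e^{kelτ₁}(e^{kelτ₂}−1)]`

  semi-noncompartmental: `F* = (AUC_oral / AUC_hyp.iv)^p` with the
  hypothetical IV bolus back-extrapolated from the post-absorption
  (t > τ) log-linear phase (default exponent p = ½, configurable);
* fraction-absorbed curves `FA(t)` that reach 1 exactly at τ;
* a synthetic-data generator with named study templates (published
  absorption schedules, documented fixture disposition constants,
  proportional + additive noise, LOQ handling) so every pipeline stage is
  testable with known ground truth.

Intended users: pharmacometricians and formulation scientists analysing
oral profiles or prototyping finite-absorption-time analyses.

## Worked example

Fit candidate models to a noisy three-stage extended-release profile and
compare with the first-order comparator (`examples/02_fit_and_compare.py`):

```text
simulated series: 15 samples, true tau = 11.6 h
               model          SSR  params       AICc
   one_compartment:1    1.253e-05       3     -201.7
   one_compartment:2    1.646e-06       5     -223.7
   one_compartment:3    2.574e-07       7     -238.2
             bateman    5.006e-05       3     -181.0

selected: one_compartment:3
fitted total absorption duration = 12.00 h (truth 11.6 h)
  stage 1: 4.70 +/- 0.14 h at 0.00093 mg/mL/h
  stage 2: 2.51 +/- 0.33 h at 0.00264 mg/mL/h
  stage 3: 4.78 +/- 0.28 h at 0.00155 mg/mL/h
```

The three-stage model wins on AICc; the Bateman fit is two orders of
magnitude worse in SSR — a single first-order constant cannot reproduce
staged release. The fitted stage durations and rates recover the simulated
truth within the noise, and their sum estimates the finite absorption time.

Bioavailability from oral data alone (`examples/03_bioavailability.py`):

```text
ketoprofen-like:  F(one-stage closed form) = 0.779
theophylline IR:  F(two-stage closed form)  = 0.912
theodur-like:     F*(AUC ratio^0.5) = 0.746 [AUC_oral=0.2099, AUC_hyp.iv=0.3773]
```

Each `F` is the fraction of the dose reaching circulation, inferred without
an intravenous reference arm. The other examples cover forward simulation
(`01`), fraction-absorbed curves (`04`), and the end-to-end report
pipeline (`05`). A thin CLI mirrors the library
(`pbftpk simulate|generate|fit|estimate-f|fa-curve|report`).

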