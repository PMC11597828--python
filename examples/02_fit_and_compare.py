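"""Fit staged models and the Bateman comparator to a noisy synthetic profile.

Generates an extended-release-like profile (three zero-order stages, 5%
proportional noise), fits 1-3-stage models plus the classical first-order
absorption curve, and shows why the staged description wins.
"""

from pbftpk import NoiseModel, compare_models, study_fixture

series, truth = study_fixture("theodur_like", NoiseModel(proportional_cv=0.05, seed=42))
print(f"simulated series: {len(series)} samples, true tau = "
      f"{truth.schedule.total_duration:.1f} h")

comparison = compare_models(
    series,
    ["one_compartment:1", "one_compartment:2", "one_compartment:3", "bateman"],
    seed=0,
)
print(f"{'model':>20} {'SSR':>12} {'params':>7} {'AICc':>10}")
for entry in comparison.entries:
    print(
        f"{entry.model_spec:>20} {entry.ssr:12.3e} {entry.n_params:7d} "
        f"{entry.information_criterion:10.1f}"
    )
best = comparison.best
print(f"\nselected: {best.model_spec}")
fit = best.fit
print(f"fitted total absorption duration = {fit.total_duration:.2f} h "
      f"(truth 11.6 h)")
for i in range(3):
    tau = fit.estimates[f"tau{i + 1}"]
    rate = fit.estimates[f"rate{i + 1}"]
    se = fit.standard_errors[f"tau{i + 1}"]
    print(f"  stage {i + 1}: {tau:.2f} +/- {se:.2f} h at {rate:.5f} mg/mL/h")
# the Bateman SSR is typically ~2 orders of magnitude worse: a single
# first-order absorption constant cannot reproduce staged release
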