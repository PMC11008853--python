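"""Calibrate the model to a synthetic chip dataset.

Two fits of the healthy-skin caffeine scenario:

1. the noise-free model curve — the multi-start calibration returns the
   generating rates essentially exactly (the scenario truths are placed
   in the uniquely identifiable regime);
2. the mean of three noisy replicates — the fitted curve matches the data
   (small V_min) but the individual rates can differ from the truth: a 6 h
   curve far from saturation pins down combinations of rates, not all four
   separately.  That practical-identifiability gap is quantified by
   `parameter_recovery_experiment`.
"""

import numpy as np

from dermakin import (
    FitConfig,
    ObservationSeries,
    generate_scenario,
    get_scenario,
    multistart_fit,
    summarize_dataset,
)

scenario = get_scenario("caffeine-rt-6h")

# --- 1. noise-free calibration recovers the shipped truth -----------------
clean = scenario.simulate()
fit0 = multistart_fit(clean, FitConfig(n_starts=20, seed=7))
rel = np.max(np.abs(fit0.params.as_array() - scenario.params.as_array())
             / scenario.params.as_array())
print("noise-free fit: V_min = %.2e, worst rate error = %.2e" % (fit0.v_min, rel))

# --- 2. noisy replicates: curve match vs rate match -----------------------
replicates, truth = generate_scenario(scenario, seed=7)
summary = summarize_dataset(replicates)
mean_curve = ObservationSeries(
    times=replicates[0].times,
    values=summary.mean[scenario.id],
    unit=replicates[0].unit,
)
fit = multistart_fit(mean_curve, FitConfig(n_starts=50, seed=7))

print("\nnoisy mean-of-3 fit:")
print("rate      truth     fitted")
for name, t, f in zip(("k_in", "k_d", "k_c", "k_out"),
                      truth.as_array(), fit.params.as_array()):
    print(f"{name:6} {t:9.4f} {f:9.4f}")
print(f"V_min = {fit.v_min:.4f}; endpoint data {mean_curve.endpoint:.1f} vs "
      f"fitted {fit.fitted.endpoint:.1f} {mean_curve.unit}")
print(f"{fit.fraction_at_minimum:.0%} of starts reached the same minimum.")
print("\nThe fitted curve reproduces the measurements even when the rate")
print("vector drifts along the sloppy direction of this short, unsaturated")
print("experiment — compare the two fits above.")
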