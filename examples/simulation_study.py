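"""Bias/power study comparing candidate estimators under selection bias.

Ratio-mode cohorts make the true detection rate ratio a configured
constant, so bias, CI coverage and superiority power are measurable.
"""

import dataclasses

import pandas as pd

from screencausal import SimulationConfig, run_simulation_study

base = SimulationConfig(n_women=20_000, n_reader_sets=30, n_readers=25,
                        effect_mode="ratio")
configs = [dataclasses.replace(base, detection_ratio=r) for r in (1.0, 1.18)]
results = run_simulation_study(configs, ("naive_crude", "overlap"),
                               reps=60, seed=42)

frame = pd.DataFrame([r.summary_row() for r in results])
print(frame[["estimator", "true_ratio", "mean_pct", "bias", "sd",
             "coverage", "rejection"]].round(3).to_string(index=False))

# Expect: the naive estimator is biased downward by ~13 points at every
# true ratio (the reading-behavior bias), with poor coverage; overlap
# weighting is unbiased with ~95% coverage, and its superiority
# rejection rate rises with the true ratio.
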