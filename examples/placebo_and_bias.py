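"""The reading-behavior bias and its correction, demonstrated by placebo.

Under a placebo configuration the AI features have no effect, yet the
crude group comparison is severely biased because readers route
normal-tagged (low-prevalence) examinations into the AI group.  Overlap
weighting on reader set + AI prediction removes the bias.
"""

from screencausal import (SimulationConfig, simulate_cohort, placebo_config,
                          analyze_endpoint)
from screencausal.simstudy import estimate_once

cfg = placebo_config(SimulationConfig(n_women=400_000))
table = simulate_cohort(cfg, seed=11)

naive_pct, nlo, nhi = estimate_once(table, "naive_crude")
print(f"naive crude detection difference:   {naive_pct:+.1f}% "
      f"({nlo:+.1f}%, {nhi:+.1f}%)   <- spurious, no true effect exists")

est, _ = analyze_endpoint(table, "detection")
print(f"overlap-weighted difference:        {est.pct_diff:+.1f}% "
      f"({est.ci_pct[0]:+.1f}%, {est.ci_pct[1]:+.1f}%)   <- correctly near zero")
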