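"""Force-trace synthesis and effort/rest epoch detection.

Simulates one noisy grip-force trial, runs the threshold-based offline
segmentation, and compares detected epoch durations with the simulator's
ground truth; then computes the trial payoff.
"""

import numpy as np

from effortalloc import (
    Condition,
    ParameterSet,
    compute_payoff,
    detect_epochs,
    simulate_force_trace,
)

params = ParameterSet(Sem=0.16, Srm=0.37, Ai=0.15, Sed=0.021, Sri=0.086)
cond = Condition(5, 0.80)

trace = simulate_force_trace(params, cond, noise_sd=0.02, rng=7)
seg = detect_epochs(trace)

print(f"condition {cond.label}: detected {seg.n_efforts} effort epochs")
print(f"  first rest (pre-onset time): {seg.first_rest:.2f} s")
for k, (on, off) in enumerate(zip(seg.onsets, seg.offsets)):
    truth = trace.true_epochs[k]
    print(f"  effort {k + 1}: {off - on:5.2f} s detected "
          f"(truth {truth[1] - truth[0]:5.2f} s)")

payoff = compute_payoff(trace, cond)
print(f"\npayoff: {payoff:.1f} units "
      f"(incentive {cond.incentive_pence}p x seconds above the force target)")
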