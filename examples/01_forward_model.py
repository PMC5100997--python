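"""Forward model: mean effort/rest durations from accumulation parameters.

Builds the winning model at the placebo group means and prints the
predicted durations over the 3x3 incentive/difficulty design, plus the
underlying cost-evidence trajectory of one trial.
"""

from effortalloc import (
    Condition,
    ParameterSet,
    cost_evidence_trajectory,
    design_conditions,
    predict_durations,
)

params = ParameterSet(Sem=0.16, Srm=0.37, Ai=0.15, Sed=0.021, Sri=0.086)

print("condition   Te (s)   Tr (s)")
for cond in design_conditions():
    pred = predict_durations(params, cond)
    print(f"{cond.label:>9}   {pred.Te:6.2f}   {pred.Tr:6.2f}")
print()
print("Te = A/Se rises with incentive (amplitude expansion) and falls with")
print("difficulty (steeper accumulation); Tr = A/Sr falls with incentive")
print("(faster dissipation).")

_, _, epochs = cost_evidence_trajectory(params, Condition(2, 0.80), 30.0)
effort = [(f"{on:.2f}-{off:.2f}" + ("*" if tr else ""))
          for on, off, kind, tr in epochs if kind == "effort"]
print(f"\nEffort epochs in one 30-s trial at 2p/80% (* = cut by trial end):")
print("  " + ", ".join(effort))
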