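"""Delta-modulation analysis: which parameter carries a group difference?

Plants a 31% reduction of the mean accumulation slope (the SSRI-like
effect) in a matched cohort, fits reference parameters on the baseline
group, and compares delta-modulation models on the treated group.
"""

from effortalloc import (
    CohortSpec,
    draw_matched_cohorts,
    fit_delta_models,
    fit_reference,
    simulate_condition_summaries,
)
from effortalloc.simulate import _subject_rng

base, treated = draw_matched_cohorts(
    CohortSpec(n_subjects=20, seed=21), param="Sem", factor=0.69
)


def summaries(params, seed):
    return [
        simulate_condition_summaries(ps, rng=_subject_rng(seed, i, v))
        for i, ps in enumerate(params)
        for v in range(3)
    ]


ref = fit_reference(summaries(base, 100))
table = fit_delta_models(summaries(treated, 200), ref)
top = table.sort_values("log_bayes_factor", ascending=False).head(5)

print("delta model      log BF vs null   fitted delta_Sem")
for _, row in top.iterrows():
    print(f"{row['model']:<15}  {row['log_bayes_factor']:13.1f}   "
          f"{row['delta_Sem']:+.3f}")
print()
print("Models that let delta_Sem vary dominate, and the fitted value is")
print("close to the planted -0.31 (a 31% slope reduction).")
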