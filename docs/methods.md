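# Methods

## The accumulation model

A single latent variable ("cost evidence") governs when effort stops and
resumes: it accumulates at slope `Se` while force is exerted, dissipates
at slope `Sr` during rest, and triggers a switch whenever it reaches the
upper or lower bound, separated by amplitude `A`.  The observable
consequences are the mean epoch durations `Te = A/Se` and `Tr = A/Sr`.
Each of `A`, `Se`, `Sr` may depend linearly on the z-scored incentive
(`I`) and difficulty (`D`) levels of a trial.  Because durations depend
only on the ratios, `(A, Se, Sr)` is identified up to a common scale;
the amplitude baseline `Am` is fixed to 1.  Units: slopes are amplitude
units per second, so `1/Sem` and `1/Srm` are baseline durations in
seconds.

Of the 64 on/off combinations of the six modulations, 20 can produce the
three robust task effects (longer effort with incentive, shorter rest
with incentive, shorter effort with difficulty): the cross of four
incentive sets {Ai,Sei,Sri}, {Ai,Sei}, {Ai,Sri}, {Sei,Sri} with five
difficulty sets {Ad,Sed,Srd}, {Ad,Sed}, {Ad,Srd}, {Sed,Srd}, {Sed}.  We
enumerate exactly this list (deterministic order: incentive set major)
rather than re-deriving admissibility; the package's model-space test
verifies by sign search that every listed member can produce all three
effects.  Z-scoring uses the sample (n−1) standard deviation of the three
design levels; the balanced design makes per-trial and per-level
z-scoring proportional, so one convention is fixed for reproducibility.

### Trajectory conventions

Simulated trials start at the lower bound; an optional initial latency
(default: the model-predicted rest duration, so that the first rest
behaves like every other rest) precedes the first effort.  The path is
truncated at the 30-s trial end and the final, censored epoch is flagged.

## Model fitting

Each subject-visit contributes 18 observations: the mean effort and rest
duration in each of the 9 cells, equally weighted.  The observation model
is `y = g(θ) + e`, `e ~ N(0, 1/τ)` with a scalar precision shared across
cells.  Inference is fixed-form variational under the Laplace
approximation: a Gaussian posterior over the free parameters, updated by
damped Gauss–Newton steps with an analytic Jacobian, alternating with a
Gamma posterior over `τ`, until the free energy changes by less than
1e−6 (cap: 200 iterations).  The converged free energy is the log model
evidence; its parameter-KL term supplies the Occam penalty, and summing
over visits gives a subject-level score (the log of the product of
per-visit evidences).

Priors are weak by design: N(0, 10²) on every free parameter and
Gamma(0.01, 0.01) on the noise precision.  The Gamma shape/rate were
chosen near the Jeffreys limit because any appreciable rate floor (e.g. a
unit rate) caps the posterior precision at roughly `n/2` and hence floors
the inferred noise sd near 0.3 s; at realistic duration-noise levels that
saturates the likelihood term and lets the Occam penalty dominate model
comparison, to the point of preferring models that miss large planted
modulations.  Initialization is method-of-moments (`Sem = 1/mean(Te)`,
`Srm = 1/mean(Tr)`, modulations at 0).  Positivity of `(A, Se, Sr)` at
the 9 design points is enforced by step halving, with a seeded perturbed
re-initialization as a last resort; fits are deterministic given data,
prior and initialization.  Inactive modulations are structural zeros,
never estimated.

## Group-level selection

Random-effects BMS treats the generating model as a random effect: a
variational scheme updates a Dirichlet posterior (uniform prior, α₀ = 1)
over model frequencies from the per-subject evidences; exceedance
probabilities are estimated from 10⁶ seeded Dirichlet draws.  Only
within-subject evidence differences matter — adding a constant to a
subject's row leaves the result unchanged (tested).

The delta-modulation analysis stacks each group's per-condition summaries
(a single shared noise variance across the stack) and fits the winning
model to the reference (placebo-like) group; the treated group is then
modelled as `P = P_REF·(1+δ)` with every subset of up to two free deltas,
reporting log Bayes factors against the all-zero null.  A stacked fit of
heterogeneous subjects is deliberately mis-specified — `E[A/Se]` across
subjects is not `A/E[Se]` — so reference values are *effective* group
parameters, not population means; the analysis is a contrast between two
stacks fitted the same way, which is why planting the group effect in a
matched cohort (same subjects, one parameter scaled) recovers the planted
−31% accurately, while two independently drawn small cohorts can let
between-cohort sampling noise compete with the effect.

## Synthetic data

Cohorts draw subject-level parameters from truncated normal populations
whose defaults are the reference group statistics of the two treatment
arms (means = published group means; between-subject sd = published s.e.m. ×
√29); draws are rejected until `(A, Se, Sr)` are positive at all design
points.  Per-condition durations are model predictions plus additive
Gaussian noise, by default with sd proportional to each cell's predicted
duration (fraction 0.03, calibrated once so that the recovery simulation
reproduces the reference sensitivity/specificity pattern).  Noise can
instead be an absolute sd or per-cell sd arrays.  Values driven
non-positive are clipped at 0.05 s and counted.  One RNG stream per
subject×visit is derived from the master seed by seed-sequence hashing,
so any subset of a cohort is reproducible in isolation.

Force traces follow the model's epoch schedule with first-order kinetics
(rise and decay time constants 0.05 s — grip contraction and release are
fast relative to epoch durations) toward a plateau at 1.05× the force
target, plus *multiplicative* noise: white Gaussian smoothed by a 0.1-s
moving average, scaled to a relative sd (default 0.02) and applied in
proportion to the instantaneous force.  Signal-dependence matters: a
resting hand produces a flat baseline, and additive baseline noise would
cross the detector's derivative threshold during rest, where the
"keep the last offset" cleanup rule would then drag effort offsets toward
the next onset.  Slow decay kinetics would likewise bias offsets late,
because the offset candidates extend down the decay tail while its
derivative exceeds one sd.  With the defaults, detected durations match
ground truth within 0.1 s in ≥95% of traces (tested).

What the generator does not emulate: within-trial fatigue or carry-over
between trials, condition-correlated residual structure (real residual
exchange between subjects is impossible without the raw data; an
approximation is the per-cell sd interface), skewed parameter
distributions, and real grip-signal artifacts (clipping, drift,
mis-calibration).  Passing tests therefore demonstrate correctness of the
pipeline's machinery under the model's own assumptions, not robustness to
every feature of real recordings.

## Epoch detection, payoff, compliance

The detector follows the offline threshold rules: onset candidates are
samples with derivative above +1 sd of the trial's derivative series and
force above half-maximum; offset candidates mirror them (derivative below
−1 sd, force below half-maximum).  Among consecutive onset candidates
before an offset, the one with minimum force is kept; among consecutive
offsets between onsets, only the last; a sustained effort receives an
offset at the trial end and is flagged truncated.  The first rest is the
time from trial onset to the first effort onset; zero-length first rests
are not counted as rest epochs.  The derivative is the first difference
times the sampling rate, its sd computed per trial; timestamps are
0-based samples, intervals half-open.  Condition summaries exclude
end-truncated epochs from duration means by default (censored), while
compliance counts include them; a visit fails QC when any condition
totals fewer than three effort or three rest epochs.  Payoff is
`k · incentive · seconds at or above the force target`; `k` is a
configuration constant and all group contrasts are invariant to it.

## Behavioral statistics

Epoch-level duration regressions (separately for effort and rest) include
incentive, difficulty, block, trial-within-block and epoch-within-trial,
all z-scored, so coefficients are standardized effect sizes in seconds
per z-unit and the intercept equals the mean duration in balanced
designs.  Rank-deficient designs raise an error naming the collinear
columns.  Group comparisons use a two-way mixed-design ANOVA (treatment
between subjects, visit within; classical Type-III engine via pingouin by
default, with an alternative random-intercept mixed-model engine using
sum-coded Wald F tests and between-within denominator dfs — the two agree
on balanced data, tested to 1e−4).  Permutation tests shuffle treatment
labels (default 10,000 permutations) and use the add-one estimator
`p = (1 + #{|perm| ≥ |obs|}) / (n_perm + 1)`.  Bonferroni thresholds
follow the reference analysis: 0.05/5 for model parameters, 0.05/6 for
behavioral measures.

## Recovery simulation

For each of the five parameters in turn, every subject's value is
inflated by 20%, noisy condition summaries are regenerated, the winning
model is refitted, and paired t-tests across subjects compare refitted
with baseline estimates for all five parameters at p < 0.05/5; hits are
significant changes in the inflated parameter, false alarms in any other.
Rates aggregate over 100 replicates per target.  Three design choices
keep the measured rates a property of the fitting procedure rather than
of simulation luck, each adopted after analysing the corresponding
artifact:

1. **Frozen noise law.** Per-cell noise sds are fixed at the *baseline*
   predictions, so the planted inflation does not alter the noise a
   subject's data carries (a residual-exchange scheme has the same
   property).  If noise scaled with the inflated predictions, the small
   finite-sample estimator bias would differ between baseline and refit
   and register as false alarms.
2. **Averaged baselines.** Baseline estimates average 12 independent
   baseline fits per subject (the reference analysis averaged per-visit
   fits).  A single-fit baseline leaves a fixed estimation error that
   every replicate's paired test inherits as a shared column shift
   (standard deviation ≈ 0.5 t-units with 3 fits), inflating some
   false-alarm columns to ~10% in unlucky realizations; 12 fits bring the
   shift sd below 0.3.
3. **Moment-matched cohorts.** `draw_recovery_baseline` standardizes each
   parameter column to the population mean and sd exactly (and rejects
   draws that would leave the admissible region under any single
   20% inflation).  The paired t-test's power is set by the cohort's
   mean-to-spread ratio, so freely drawn 29-subject cohorts would turn
   hit rates into cohort lotteries.

With the defaults, hit rates for the amplitude-incentive, both mean
slopes and the dissipation-incentive parameters reach ~100%, the
small-magnitude difficulty modulation is the hardest to detect, false
alarms stay at a few percent, and the median recovered change on the
diagonal is +20%.

## Numerical and interface choices

Degenerate inputs: zero-variance level sets, all-equal ANOVA responses,
empty conditions, non-finite evidences and invalid parameter regions all
raise (or, for the constant-response ANOVA, return an explicit null
result).  Currency is pence internally.  CSV is the canonical tabular
format, JSON for manifests and diagnostics, HDF5 optional for traces;
deposited MAT-format source files are ingested read-only into tidy long
tables with name heuristics and an explicit mapping override.  The
command-line layer is a thin composition of the library (simulate /
detect / fit / select / delta / recover / report).

## Problem sizes

Default study-scale settings are 29 subjects per arm, 3 visits, 8 blocks
× 9 conditions of 30-s trials, 100 recovery replicates per target,
10,000 permutations and 10⁶ Dirichlet draws.  The test suite exercises
the same code paths at reduced sizes (cohorts of 8–29 subjects, 1–3
visits, 2–100 replicates) chosen so the whole suite completes in about a
minute while the acceptance checks still run the recovery simulation at
full scale.

## Known limitations

The evidence scale depends on the (unreported) prior and noise model of
the original toolbox runs, so model *rankings* are expected to transfer
but absolute evidences and Bayes-factor magnitudes are not; a penalized
least-squares + BIC surrogate can be swapped in through the same fitting
interface for robustness checks.  The stacked reference fit uses a single
noise variance across subjects.  Mean durations are not capped at the
trial length, so extreme parameter draws can predict epochs longer than a
trial; the compliance filter, not the generator, is the guard against
such subjects in real data.  The mixed-model engine reports Wald F with
between-within dfs rather than a true Satterthwaite correction.
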