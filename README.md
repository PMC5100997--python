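# effortalloc

Computational analysis of effort allocation under pharmacological
treatment, built around a bounded cost-evidence accumulation model of
handgrip performance.

In the underlying task, participants spend 30-second trials freely
alternating between squeezing a handgrip and resting; payoff is
proportional to the monetary incentive (1, 2 or 5 pence per trial) and the
time spent above a force target (70, 80 or 90% of maximal force).  The
model explains how effort is chunked over time: a latent *cost evidence*
signal rises during effort with slope `Se` and falls during rest with
slope `Sr`, bouncing between bounds separated by an amplitude `A`.  Mean
effort and rest durations are therefore

```
Te = A / Se        Tr = A / Sr

A  = Am + Ai·I                (Am fixed to 1 for identifiability)
Se = Sem + Sed·D
Sr = Srm + Sri·I
```

with `I` and `D` the z-scored incentive and difficulty levels.  This
winning parameterization is one of 20 admissible combinations (out of
2^6 = 64) of linear factor modulations; the package enumerates the whole
family, fits each model per subject-visit with a variational-Bayes
(Laplace) scheme whose free energy approximates the log model evidence,
aggregates evidence over visits, and performs group-level random-effects
Bayesian model selection (exceedance probabilities via a Dirichlet
posterior).  Treatment effects are localized with delta-modulation models
(`P = P_REF · (1 + δ)` against placebo-fitted reference values, compared
by log Bayes factors) and validated by a parameter-recovery simulation
that plants 20% changes and tabulates hit and false-alarm rates.

The package is aimed at computational-psychiatry researchers who want to
reuse the pipeline on their own force-signal data or audit its behavior on
synthetic cohorts; every stage (trace synthesis, epoch detection, payoff,
compliance QC, duration regressions, group statistics, model fitting,
selection, recovery) is exposed as an importable API with a thin
`effortalloc` command-line layer on top.

## Worked example

Fitting the 20-model family to a 12-subject synthetic cohort generated
from the winning model, then selecting at the group level
(`examples/03_fit_and_select.py`):

```
model            E[freq]    xp
AiSedSri          0.402   0.998
SeiSedSri         0.034   0.000
AiSeiSedSriSrd    0.031   0.000
...
mean fitted accumulation slope Sem: 0.170 (true population mean 0.16)
```

`xp` is the exceedance probability — the posterior probability that a
model is the most frequent in the population; the generating model
(amplitude and dissipation modulated by incentive, accumulation by
difficulty) wins decisively, and the recovered mean accumulation slope is
close to the population value it was simulated from.

Planting an SSRI-like 31% reduction of the mean accumulation slope in a
matched cohort and asking which single parameter explains the group
difference (`examples/04_treatment_effect.py`):

```
delta model      log BF vs null   fitted delta_Sem
dSem                      52.4   -0.360
dSem+dSed                 48.8   -0.352
dAi+dSem                  48.8   -0.360
```

Models freeing `δ_Sem` dominate and the fitted modulation is close to the
planted −0.31, i.e. the pipeline attributes the group difference to the
effort-cost accumulation rate, not to incentive weighting.

The other examples cover the forward model, trace synthesis plus epoch
detection, the recovery simulation, and the behavioral statistics; each
prints a few numbers with a line on what they mean.

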