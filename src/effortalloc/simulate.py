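"""Synthetic cohorts, condition summaries and raw force traces.

The generator emulates the effort-allocation task: 30-s trials, 8 blocks of
the 9 crossed incentive (1/2/5 pence) x difficulty (70/80/90% of maximal
force) conditions.  Subject-level parameters are drawn from truncated
normal populations whose defaults are anchored to the published group
statistics of the placebo and escitalopram (SSRI) arms: means equal to the
published group means and between-subject standard deviations equal to
the published s.e.m. times sqrt(n = 29).

Per-condition mean durations are the model predictions corrupted with
additive Gaussian noise; by default the noise sd is proportional to each
cell's predicted duration (fraction 0.03), a magnitude calibrated so that
the parameter-recovery simulation reproduces the published
sensitivity/specificity pattern.  Force traces follow the cost-evidence
epoch schedule with first-order rise/decay kinetics and band-limited
(moving-average smoothed) Gaussian noise emulating slow grip tremor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import ConditionSummary
from .model import (
    BEST_MODEL,
    Condition,
    ParameterSet,
    cost_evidence_trajectory,
    design_conditions,
    predict_durations,
)

__all__ = [
    "PLACEBO_POPULATION",
    "ESCITALOPRAM_POPULATION",
    "CohortSpec",
    "SyntheticDataset",
    "ForceTrace",
    "draw_parameters",
    "draw_matched_cohorts",
    "simulate_condition_summaries",
    "simulate_cohort",
    "simulate_force_trace",
    "DEFAULT_NOISE_FRAC",
]

# Published group means and s.e.m. (n = 29 per arm) for the five free
# parameters of the winning model; between-subject sd = s.e.m. * sqrt(29).
_SQRT_N = np.sqrt(29.0)
PLACEBO_POPULATION = {
    "Sem": (0.16, 0.012 * _SQRT_N),
    "Srm": (0.37, 0.022 * _SQRT_N),
    "Ai": (0.15, 0.028 * _SQRT_N),
    "Sed": (0.021, 0.004 * _SQRT_N),
    "Sri": (0.086, 0.018 * _SQRT_N),
}
ESCITALOPRAM_POPULATION = {
    "Sem": (0.11, 0.008 * _SQRT_N),
    "Srm": (0.42, 0.029 * _SQRT_N),
    "Ai": (0.19, 0.022 * _SQRT_N),
    "Sed": (0.013, 0.002 * _SQRT_N),
    "Sri": (0.126, 0.016 * _SQRT_N),
}

#: Default duration-noise sd as a fraction of each cell's predicted duration.
DEFAULT_NOISE_FRAC = 0.03

#: Floor used when additive noise would produce a non-positive duration, s.
_CLIP_FLOOR = 0.05


@dataclass(frozen=True)
class CohortSpec:
    """Population description for one synthetic treatment arm."""

    group: str = "placebo"
    n_subjects: int = 29
    population: dict = None           # parameter -> (mean, between-subject sd)
    duration_noise_frac: float | None = DEFAULT_NOISE_FRAC
    duration_noise_sd: float | None = None   # absolute sd (s); overrides frac
    n_visits: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.population is None:
            pop = (ESCITALOPRAM_POPULATION if self.group.lower().startswith("esc")
                   else PLACEBO_POPULATION)
            object.__setattr__(self, "population", dict(pop))
        for k, (m, s) in self.population.items():
            if s < 0:
                raise ValueError(f"negative sd for {k}")


def _subject_rng(seed: int, subject: int, visit: int = 0) -> np.random.Generator:
    """One reproducible stream per subject x visit (SeedSequence hashing)."""
    return np.random.default_rng(np.random.SeedSequence([seed, subject, visit]))


def draw_parameters(spec: CohortSpec) -> list[ParameterSet]:
    """Draw one ParameterSet per subject from the truncated-normal population.

    Draws are rejected until A, Se and Sr are positive at every design
    condition; if the admissible region holds essentially no mass the draw
    errors out instead of looping forever.
    """
    out = []
    conds = design_conditions()
    for s in range(spec.n_subjects):
        rng = _subject_rng(spec.seed, s)
        for attempt in range(100_000):
            vals = {k: rng.normal(m, sd) for k, (m, sd) in spec.population.items()}
            ps = ParameterSet(
                Sem=vals.get("Sem", 0.16),
                Srm=vals.get("Srm", 0.37),
                Ai=vals.get("Ai", 0.0),
                Ad=vals.get("Ad", 0.0),
                Sei=vals.get("Sei", 0.0),
                Sed=vals.get("Sed", 0.0),
                Sri=vals.get("Sri", 0.0),
                Srd=vals.get("Srd", 0.0),
            )
            if ps.is_valid(conds):
                out.append(ps)
                break
        else:
            raise ValueError(
                "truncation infeasible: admissible region has negligible mass"
            )
    return out


def draw_matched_cohorts(
    spec: CohortSpec, param: str = "Sem", factor: float = 0.69
) -> tuple[list[ParameterSet], list[ParameterSet]]:
    """Baseline cohort plus a matched cohort with one parameter scaled.

    Each subject is drawn from ``spec``'s population with rejection until
    both the baseline parameters and the variant with ``param`` multiplied
    by ``factor`` are admissible; the second list holds the scaled twins.
    Used to plant a pure single-parameter group effect (e.g. the 31%
    accumulation-slope reduction seen under SSRI treatment corresponds to
    ``factor=0.69`` on ``Sem``).
    """
    from dataclasses import replace as _replace

    conds = design_conditions()
    base, scaled = [], []
    for s in range(spec.n_subjects):
        rng = _subject_rng(spec.seed, s)
        for _ in range(100_000):
            vals = {k: rng.normal(m, sd) for k, (m, sd) in spec.population.items()}
            ps = ParameterSet(
                Sem=vals.get("Sem", 0.16), Srm=vals.get("Srm", 0.37),
                Ai=vals.get("Ai", 0.0), Ad=vals.get("Ad", 0.0),
                Sei=vals.get("Sei", 0.0), Sed=vals.get("Sed", 0.0),
                Sri=vals.get("Sri", 0.0), Srd=vals.get("Srd", 0.0),
            )
            twin = _replace(ps, **{param: getattr(ps, param) * factor})
            if ps.is_valid(conds) and twin.is_valid(conds):
                base.append(ps)
                scaled.append(twin)
                break
        else:
            raise ValueError("matched-cohort truncation infeasible")
    return base, scaled


def _noise_scale(pred: np.ndarray, spec_or_frac, noise_sd=None) -> np.ndarray:
    if noise_sd is not None:
        # scalar or per-cell array of absolute sds
        return np.broadcast_to(np.asarray(noise_sd, dtype=float), pred.shape)
    frac = spec_or_frac if spec_or_frac is not None else 0.0
    return frac * pred


def simulate_condition_summaries(
    params: ParameterSet,
    conditions: list[Condition] | None = None,
    noise_frac: float | None = DEFAULT_NOISE_FRAC,
    noise_sd: float | None = None,
    rng: np.random.Generator | int | None = 0,
) -> ConditionSummary:
    """Model-predicted per-condition durations plus additive Gaussian noise.

    ``noise_sd`` (absolute, seconds) overrides ``noise_frac`` (fraction of
    each cell's predicted duration); it may be a scalar, or a
    ``(te_sds, tr_sds)`` pair of per-cell arrays for heteroscedastic noise
    whose law is fixed externally (e.g. tied to a baseline parameter set,
    as in the recovery simulation).  Values that noise drives non-positive
    are clipped to a small floor; the number of clipped cells is recorded on
    the returned object as ``n_clipped``.
    """
    conds = conditions if conditions is not None else design_conditions()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    preds = [predict_durations(params, c) for c in conds]
    te = np.array([p.Te for p in preds])
    tr = np.array([p.Tr for p in preds])
    if isinstance(noise_sd, tuple):
        te_sd, tr_sd = noise_sd
    else:
        te_sd = tr_sd = noise_sd
    te_noisy = te + rng.normal(0.0, 1.0, te.size) * _noise_scale(te, noise_frac, te_sd)
    tr_noisy = tr + rng.normal(0.0, 1.0, tr.size) * _noise_scale(tr, noise_frac, tr_sd)
    n_clipped = int(np.sum(te_noisy < _CLIP_FLOOR) + np.sum(tr_noisy < _CLIP_FLOOR))
    te_noisy = np.maximum(te_noisy, _CLIP_FLOOR)
    tr_noisy = np.maximum(tr_noisy, _CLIP_FLOOR)
    summ = ConditionSummary(conditions=conds, te=te_noisy, tr=tr_noisy)
    summ.n_clipped = n_clipped
    return summ


@dataclass
class SyntheticDataset:
    """A simulated cohort: true parameters and per-visit condition summaries."""

    spec: CohortSpec
    parameters: list[ParameterSet]
    summaries: dict            # subject index -> list of ConditionSummary

    @property
    def n_subjects(self) -> int:
        return len(self.parameters)


def simulate_cohort(spec: CohortSpec) -> SyntheticDataset:
    """Generate a full cohort: parameter draws + noisy summaries per visit.

    Subject-level parameters are constant across visits; visit-level
    variability enters through the duration noise.  Fully determined by
    ``spec.seed``.
    """
    params = draw_parameters(spec)
    summaries = {}
    for s, ps in enumerate(params):
        summaries[s] = [
            simulate_condition_summaries(
                ps,
                noise_frac=spec.duration_noise_frac,
                noise_sd=spec.duration_noise_sd,
                rng=_subject_rng(spec.seed, s, visit + 1),
            )
            for visit in range(spec.n_visits)
        ]
    return SyntheticDataset(spec=spec, parameters=params, summaries=summaries)


@dataclass
class ForceTrace:
    """A sampled, normalized grip-force signal for one 30-s trial."""

    t: np.ndarray
    f: np.ndarray
    fs: float
    cond: Condition
    block: int = 0
    trial: int = 0
    true_epochs: list = None    # ground-truth (onset, offset, kind, truncated)

    @property
    def trial_length(self) -> float:
        return float(self.t[-1] + 1.0 / self.fs)


def simulate_force_trace(
    params: ParameterSet,
    cond: Condition,
    trial_length: float = 30.0,
    fs: float = 100.0,
    initial_latency: float | str = "model",
    tau_rise: float = 0.05,
    tau_decay: float = 0.05,
    overshoot: float = 1.05,
    noise_sd: float = 0.02,
    noise_smooth_s: float = 0.1,
    rng: np.random.Generator | int | None = 0,
) -> ForceTrace:
    """Synthesize a grip-force trace following the model's epoch schedule.

    Effort epochs drive the force toward a plateau at
    ``overshoot * difficulty_frac`` with first-order rise time constant
    ``tau_rise``; rest epochs decay toward 0 with ``tau_decay`` (grip
    contraction and release are fast, of order 50 ms).  Noise is
    multiplicative — white Gaussian smoothed with a ``noise_smooth_s``
    moving average, scaled to relative sd ``noise_sd`` and applied in
    proportion to the instantaneous force — reflecting signal-dependent
    motor noise: a resting hand produces a flat baseline, while tremor
    grows with the exerted force.  ``initial_latency="model"`` sets the
    pre-onset rest to the model-predicted rest duration Tr.

    Raises ``ValueError`` when the plateau does not exceed 0.5 normalized
    force (such efforts are undetectable by the half-maximum rule and signal
    a mis-specified simulation).
    """
    if fs < 20:
        raise ValueError("sampling rate must be at least 20 Hz")
    plateau = overshoot * cond.difficulty_frac
    if plateau <= 0.5:
        raise ValueError("effort plateau must exceed 0.5 normalized force")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if initial_latency == "model":
        initial_latency = predict_durations(params, cond).Tr
    _, _, epochs = cost_evidence_trajectory(
        params, cond, trial_length=trial_length,
        initial_latency=float(initial_latency),
    )
    n = int(round(trial_length * fs))
    t = np.arange(n) / fs
    target = np.zeros(n)
    for onset, offset, kind, _trunc in epochs:
        if kind == "effort":
            i0, i1 = int(round(onset * fs)), int(round(offset * fs))
            target[i0:i1] = plateau
    # first-order tracking of the target level
    f = np.zeros(n)
    a_rise = 1.0 - np.exp(-1.0 / (fs * tau_rise))
    a_decay = 1.0 - np.exp(-1.0 / (fs * tau_decay))
    level = 0.0
    for i in range(n):
        alpha = a_rise if target[i] > level else a_decay
        level = level + alpha * (target[i] - level)
        f[i] = level
    if noise_sd > 0:
        w = max(1, int(round(noise_smooth_s * fs)))
        raw = rng.normal(0.0, 1.0, n + w)
        kernel = np.ones(w) / w
        smooth = np.convolve(raw, kernel, mode="valid")[:n]
        sd = smooth.std()
        if sd > 0:
            f = f * (1.0 + noise_sd * smooth / sd)
    f = np.clip(f, 0.0, None)
    effort_epochs = [e for e in epochs if e[2] == "effort"]
    return ForceTrace(t=t, f=f, fs=fs, cond=cond, true_epochs=effort_epochs)
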