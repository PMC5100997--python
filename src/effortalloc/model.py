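"""Cost-evidence accumulation model of effort allocation.

During a trial, a latent decision variable ("cost evidence") accumulates at
slope ``Se`` while the subject squeezes the grip and dissipates at slope
``Sr`` while the subject rests.  Effort stops when cost evidence hits an
upper bound and resumes when it returns to the lower bound; the distance
between bounds is the amplitude ``A``.  Mean effort and rest durations are
therefore

    Te = A / Se          Tr = A / Sr

with each of ``A``, ``Se``, ``Sr`` optionally a linear function of the
z-scored incentive (``I``) and difficulty (``D``) levels::

    A  = Am + Ai*I + Ad*D
    Se = Sem + Sei*I + Sed*D
    Sr = Srm + Sri*I + Srd*D

Because durations only depend on the ratios A/Se and A/Sr, the triple
(A, Se, Sr) is defined up to a common scale; the baseline amplitude ``Am``
is fixed to 1 for identifiability.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "INCENTIVE_LEVELS",
    "DIFFICULTY_LEVELS",
    "Condition",
    "ModelSpec",
    "ParameterSet",
    "DurationPrediction",
    "BEST_MODEL",
    "MODULATION_NAMES",
    "zscore_levels",
    "design_conditions",
    "predict_durations",
    "enumerate_model_space",
    "enumerate_unconstrained_space",
    "cost_evidence_trajectory",
]

#: Task factor levels: coin value in pence and force target as a fraction of
#: the subject's maximal force.
INCENTIVE_LEVELS = (1, 2, 5)
DIFFICULTY_LEVELS = (0.70, 0.80, 0.90)

MODULATION_NAMES = ("Ai", "Ad", "Sei", "Sed", "Sri", "Srd")


def zscore_levels(levels) -> np.ndarray:
    """Z-score a set of design levels (sample sd, n-1 denominator).

    Raises ``ValueError`` on fewer than two distinct values (zero variance).
    """
    x = np.asarray(levels, dtype=float)
    if x.size < 2 or np.ptp(x) == 0.0:
        raise ValueError("z-scoring requires at least two distinct levels")
    return (x - x.mean()) / x.std(ddof=1)


_I_Z = zscore_levels(INCENTIVE_LEVELS)
_D_Z = zscore_levels(DIFFICULTY_LEVELS)


@dataclass(frozen=True)
class Condition:
    """One cell of the 3 incentive x 3 difficulty design.

    ``I`` and ``D`` are the z-scored covariates entering the linear
    modulations; they are deterministic functions of the raw levels.
    """

    incentive_pence: int
    difficulty_frac: float
    I: float = field(init=False)
    D: float = field(init=False)

    def __post_init__(self):
        if self.incentive_pence not in INCENTIVE_LEVELS:
            raise ValueError(f"incentive must be one of {INCENTIVE_LEVELS}")
        try:
            di = DIFFICULTY_LEVELS.index(round(self.difficulty_frac, 2))
        except ValueError:
            raise ValueError(f"difficulty must be one of {DIFFICULTY_LEVELS}")
        ii = INCENTIVE_LEVELS.index(self.incentive_pence)
        object.__setattr__(self, "I", float(_I_Z[ii]))
        object.__setattr__(self, "D", float(_D_Z[di]))

    @property
    def label(self) -> str:
        return f"{self.incentive_pence}p/{int(round(self.difficulty_frac * 100))}%"


def design_conditions() -> list[Condition]:
    """The 9 conditions of the fully crossed design, incentive-major order."""
    return [
        Condition(i, d) for i in INCENTIVE_LEVELS for d in DIFFICULTY_LEVELS
    ]


@dataclass(frozen=True)
class ModelSpec:
    """Which of the six factor modulations a model allows.

    Every model additionally has the mean slopes ``Sem`` and ``Srm`` free and
    ``Am`` fixed to 1.  Inactive modulations are structural zeros, never
    fitted.
    """

    has_Ai: bool = False
    has_Ad: bool = False
    has_Sei: bool = False
    has_Sed: bool = False
    has_Sri: bool = False
    has_Srd: bool = False

    @property
    def active(self) -> tuple[str, ...]:
        return tuple(m for m in MODULATION_NAMES if getattr(self, f"has_{m}"))

    @property
    def free_parameters(self) -> tuple[str, ...]:
        """Names of the free parameters, in fitting order."""
        return ("Sem", "Srm") + self.active

    @property
    def name(self) -> str:
        """Flag-string serialization, e.g. ``"AiSedSri"`` (``"null"`` if none)."""
        return "".join(self.active) or "null"

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        flags = {}
        rest = name if name != "null" else ""
        while rest:
            for m in MODULATION_NAMES:
                if rest.startswith(m):
                    flags[f"has_{m}"] = True
                    rest = rest[len(m):]
                    break
            else:
                raise ValueError(f"cannot parse model name {name!r}")
        return cls(**flags)


#: The winning model: incentive expands the amplitude (Ai) and speeds the
#: dissipation (Sri); difficulty steepens the accumulation (Sed).
BEST_MODEL = ModelSpec(has_Ai=True, has_Sed=True, has_Sri=True)

# Admissible factor-effect combinations: each must be able to produce the
# three qualitative task effects (Te up with incentive, Tr down with
# incentive, Te down with difficulty).
_INCENTIVE_COMBOS = (
    ("Ai", "Sei", "Sri"),
    ("Ai", "Sei"),
    ("Ai", "Sri"),
    ("Sei", "Sri"),
)
_DIFFICULTY_COMBOS = (
    ("Ad", "Sed", "Srd"),
    ("Ad", "Sed"),
    ("Ad", "Srd"),
    ("Sed", "Srd"),
    ("Sed",),
)


def enumerate_model_space() -> list[ModelSpec]:
    """The 20 admissible models: 4 incentive x 5 difficulty combinations.

    Ordering is deterministic: incentive combination major, difficulty
    combination minor.
    """
    specs = []
    for inc in _INCENTIVE_COMBOS:
        for dif in _DIFFICULTY_COMBOS:
            flags = {f"has_{m}": True for m in inc + dif}
            specs.append(ModelSpec(**flags))
    return specs


def enumerate_unconstrained_space() -> list[ModelSpec]:
    """All 2^6 = 64 on/off combinations of the six modulations."""
    return [
        ModelSpec(**{f"has_{m}": bool(b) for m, b in zip(MODULATION_NAMES, bits)})
        for bits in itertools.product((0, 1), repeat=len(MODULATION_NAMES))
    ]


@dataclass(frozen=True)
class ParameterSet:
    """Latent parameters of the accumulation model.

    ``Am`` is the fixed amplitude baseline (1 by construction); the ``*m``
    parameters are the mean slopes (amplitude units per second) and the
    ``*i`` / ``*d`` parameters the linear modulations by z-scored incentive
    and difficulty.  Inactive modulations are exactly 0.
    """

    Sem: float
    Srm: float
    Am: float = 1.0
    Ai: float = 0.0
    Ad: float = 0.0
    Sei: float = 0.0
    Sed: float = 0.0
    Sri: float = 0.0
    Srd: float = 0.0

    def slopes_at(self, I, D):
        """(A, Se, Sr) evaluated at z-scored covariates I, D (broadcasting)."""
        I = np.asarray(I, dtype=float)
        D = np.asarray(D, dtype=float)
        A = self.Am + self.Ai * I + self.Ad * D
        Se = self.Sem + self.Sei * I + self.Sed * D
        Sr = self.Srm + self.Sri * I + self.Srd * D
        return A, Se, Sr

    def is_valid(self, conditions=None) -> bool:
        """True if A, Se, Sr are all positive at every design condition."""
        conds = conditions if conditions is not None else design_conditions()
        I = np.array([c.I for c in conds])
        D = np.array([c.D for c in conds])
        A, Se, Sr = self.slopes_at(I, D)
        return bool(np.all(A > 0) and np.all(Se > 0) and np.all(Sr > 0))

    def as_dict(self) -> dict[str, float]:
        return {
            k: getattr(self, k)
            for k in ("Am", "Ai", "Ad", "Sem", "Sei", "Sed", "Srm", "Sri", "Srd")
        }


@dataclass(frozen=True)
class DurationPrediction:
    """Mean effort (Te) and rest (Tr) epoch durations, in seconds."""

    Te: float
    Tr: float


def predict_durations(params: ParameterSet, cond: Condition) -> DurationPrediction:
    """Mean effort/rest durations Te = A/Se, Tr = A/Sr at one condition.

    Raises ``ValueError`` if any of A, Se, Sr is non-positive at the
    condition (invalid parameterization).
    """
    A, Se, Sr = params.slopes_at(cond.I, cond.D)
    if not (A > 0 and Se > 0 and Sr > 0):
        raise ValueError(
            f"non-positive latent quantity at {cond.label}: A={A}, Se={Se}, Sr={Sr}"
        )
    return DurationPrediction(Te=float(A / Se), Tr=float(A / Sr))


def cost_evidence_trajectory(
    params: ParameterSet,
    cond: Condition,
    trial_length: float = 30.0,
    initial_latency: float = 0.0,
):
    """Piecewise-linear cost-evidence path and its effort/rest schedule.

    The path starts at the lower bound (0); after ``initial_latency`` seconds
    of pre-onset rest, it rises at slope +Se to the upper bound A (effort),
    then falls at slope -Sr back to 0 (rest), repeating until truncation at
    ``trial_length``.

    Returns ``(times, values, epochs)`` where ``epochs`` is a list of
    ``(onset, offset, kind, truncated)`` with ``kind`` in {"effort", "rest"}.
    """
    if trial_length <= 0:
        raise ValueError("trial_length must be positive")
    if initial_latency < 0:
        raise ValueError("initial_latency must be non-negative")
    A, Se, Sr = params.slopes_at(cond.I, cond.D)
    if not (A > 0 and Se > 0 and Sr > 0):
        raise ValueError("invalid parameters at condition")
    Te, Tr = A / Se, A / Sr

    times, values = [0.0], [0.0]
    epochs = []
    t = 0.0
    if initial_latency > 0:
        t = min(initial_latency, trial_length)
        epochs.append((0.0, t, "rest", initial_latency > trial_length))
        times.append(t)
        values.append(0.0)
    effort = True
    while t < trial_length:
        dur = Te if effort else Tr
        end = t + dur
        truncated = end > trial_length
        end = min(end, trial_length)
        level = A if effort else 0.0
        if truncated:
            frac = (end - t) / dur
            level = values[-1] + (level - values[-1]) * frac
        times.append(end)
        values.append(level)
        epochs.append((t, end, "effort" if effort else "rest", truncated))
        t = end
        effort = not effort
    return np.asarray(times), np.asarray(values), epochs
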