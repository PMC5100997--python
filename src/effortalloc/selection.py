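"""Group-level model selection and treatment-effect localization.

Two group analyses:

* Random-effects Bayesian model selection (RFX-BMS): the generating model is
  treated as a random effect across subjects.  A variational scheme updates
  a Dirichlet posterior over model frequencies from the per-subject log
  evidences; the headline statistic is the exceedance probability (xp), the
  posterior probability that a model is the most frequent in the population,
  estimated by Monte-Carlo sampling of the Dirichlet posterior.

* Delta-modulation analysis: the winning model is fitted to the placebo
  group's stacked condition summaries to obtain reference values
  (Ai_REF, Sem_REF, Sed_REF, Srm_REF, Sri_REF); the treated group is then
  modelled with each parameter equal to REF * (1 + delta), where only a
  small subset of deltas (size 0, 1 or 2) is free.  Log Bayes factors
  against the all-deltas-zero null localize which parameter carries the
  group difference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma

from .data import ConditionSummary
from .fitting import EvidenceMatrix, FitResult, Prior, vb_fit
from .model import BEST_MODEL, ModelSpec, ParameterSet

__all__ = [
    "BMSResult",
    "rfx_bms",
    "stack_summaries",
    "fit_reference",
    "DeltaFit",
    "fit_delta_models",
    "DELTA_PARAMETERS",
]

DELTA_PARAMETERS = ("Ai", "Sem", "Sed", "Srm", "Sri")


@dataclass
class BMSResult:
    """Dirichlet posterior over model frequencies and exceedance probabilities."""

    alpha: np.ndarray              # Dirichlet concentration per model
    expected_freq: np.ndarray      # E[model frequency]
    xp: np.ndarray                 # exceedance probability per model
    model_names: list
    n_iter: int
    converged: bool

    @property
    def best_index(self) -> int:
        return int(np.argmax(self.xp))


def rfx_bms(
    logE,
    model_names=None,
    alpha0: float = 1.0,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_draws: int = 1_000_000,
    seed: int = 0,
) -> BMSResult:
    """Random-effects BMS via the variational Dirichlet scheme.

    ``logE`` is a (subjects x models) matrix of log model evidences (an
    :class:`~effortalloc.fitting.EvidenceMatrix` is accepted).  Only
    within-subject evidence differences matter: adding a constant to a row
    leaves the result unchanged.  Exceedance probabilities are estimated
    from ``n_draws`` Monte-Carlo samples of the Dirichlet posterior.
    """
    if isinstance(logE, EvidenceMatrix):
        if model_names is None:
            model_names = logE.model_names
        logE = logE.logE
    logE = np.asarray(logE, dtype=float)
    if logE.ndim != 2 or logE.shape[0] < 2 or logE.shape[1] < 2:
        raise ValueError("need a (>=2 subjects) x (>=2 models) evidence matrix")
    if not np.all(np.isfinite(logE)):
        bad = np.argwhere(~np.isfinite(logE))[0]
        raise ValueError(
            f"non-finite log evidence for subject {bad[0]}, model {bad[1]}"
        )
    n, K = logE.shape
    if model_names is None:
        model_names = [f"model{k}" for k in range(K)]
    alpha = np.full(K, alpha0, dtype=float)
    converged = False
    for it in range(1, max_iter + 1):
        w = logE + digamma(alpha) - digamma(alpha.sum())
        w = w - w.max(axis=1, keepdims=True)
        u = np.exp(w)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            converged = True
            break
        alpha = alpha_new
    rng = np.random.default_rng(seed)
    counts = np.zeros(K, dtype=np.int64)
    remaining = int(n_draws)
    while remaining > 0:
        m = min(remaining, 200_000)
        draws = rng.dirichlet(alpha, size=m)
        counts += np.bincount(np.argmax(draws, axis=1), minlength=K)
        remaining -= m
    xp = counts / n_draws
    return BMSResult(
        alpha=alpha, expected_freq=alpha / alpha.sum(), xp=xp,
        model_names=list(model_names), n_iter=it, converged=converged,
    )


def stack_summaries(summaries) -> ConditionSummary:
    """Concatenate condition summaries across subjects (and visits).

    The stacked object repeats the design conditions once per input summary
    and is fitted with a single shared noise variance.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("need at least one summary")
    conds = [c for s in summaries for c in s.conditions]
    te = np.concatenate([s.te for s in summaries])
    tr = np.concatenate([s.tr for s in summaries])
    return ConditionSummary(conditions=conds, te=te, tr=tr)


def fit_reference(
    summaries,
    spec: ModelSpec = BEST_MODEL,
    prior: Prior = Prior(),
) -> FitResult:
    """Fit the winning model to a group's stacked condition summaries.

    The posterior means serve as the reference parameter values for the
    delta-modulation analysis.
    """
    from .fitting import fit_model

    return fit_model(spec, stack_summaries(summaries), prior=prior)


@dataclass
class DeltaFit:
    """One delta-modulation model: which deltas were free and the result."""

    free_deltas: tuple
    deltas: dict
    logev: float
    log_bayes_factor: float = np.nan   # vs the all-zero null


def _delta_predict_factory(ref: ParameterSet, free, I, D):
    """g(delta) and Jacobian for parameters REF * (1 + delta)."""
    ref_vals = {k: getattr(ref, k) for k in DELTA_PARAMETERS}

    def predict(theta):
        vals = dict(ref_vals)
        for k, v in zip(free, theta):
            vals[k] = ref_vals[k] * (1.0 + v)
        A = 1.0 + vals["Ai"] * I
        Se = vals["Sem"] + vals["Sed"] * D
        Sr = vals["Srm"] + vals["Sri"] * I
        if np.any(A <= 0) or np.any(Se <= 0) or np.any(Sr <= 0):
            return None, None
        g = np.concatenate([A / Se, A / Sr])
        z = np.zeros(I.size)
        cols = []
        for k in free:
            r = ref_vals[k]
            if k == "Ai":
                cols.append(r * np.concatenate([I / Se, I / Sr]))
            elif k == "Sem":
                cols.append(r * np.concatenate([-A / Se**2, z]))
            elif k == "Sed":
                cols.append(r * np.concatenate([-A * D / Se**2, z]))
            elif k == "Srm":
                cols.append(r * np.concatenate([z, -A / Sr**2]))
            elif k == "Sri":
                cols.append(r * np.concatenate([z, -A * I / Sr**2]))
        J = np.column_stack(cols) if cols else np.zeros((2 * I.size, 0))
        return g, J

    return predict


def fit_delta_models(
    summaries,
    ref: ParameterSet | FitResult,
    max_modulations: int = 2,
    prior: Prior = Prior(),
) -> pd.DataFrame:
    """Fit every delta-subset model of size 0..max_modulations to a group.

    ``summaries`` are the treated group's per-subject-visit condition
    summaries, stacked and fitted with a single noise variance.  Returns a
    table with one row per delta subset: the free deltas, their posterior
    means, the log evidence and the log Bayes factor against the null
    (all deltas = 0).
    """
    if isinstance(ref, FitResult):
        ref = ref.params
    stacked = stack_summaries(summaries)
    I, D = stacked.I, stacked.D
    y = np.concatenate([stacked.te, stacked.tr])
    rows = []
    subsets = [()]
    for size in range(1, max_modulations + 1):
        subsets.extend(itertools.combinations(DELTA_PARAMETERS, size))
    for free in subsets:
        predict = _delta_predict_factory(ref, free, I, D)
        theta0 = np.zeros(len(free))
        mu, Sigma, F, Etau, r, conv, n_iter = vb_fit(
            y, predict, len(free), prior=prior, theta0=theta0,
        )
        rows.append(
            DeltaFit(
                free_deltas=free,
                deltas=dict(zip(free, mu)),
                logev=F,
            )
        )
    null_logev = rows[0].logev
    records = []
    for fit in rows:
        fit.log_bayes_factor = fit.logev - null_logev
        rec = {
            "model": "+".join(f"d{k}" for k in fit.free_deltas) or "null",
            "n_deltas": len(fit.free_deltas),
            "logev": fit.logev,
            "log_bayes_factor": fit.log_bayes_factor,
        }
        for k in DELTA_PARAMETERS:
            rec[f"delta_{k}"] = fit.deltas.get(k, 0.0 if fit.free_deltas else 0.0)
        records.append(rec)
    return pd.DataFrame.from_records(records)
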