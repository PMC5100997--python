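"""Model-free behavioral analysis and group statistics.

Per subject-visit, epoch-level effort and rest durations are regressed on
the task factors (incentive, difficulty) and temporal factors (block
number, trial within block, epoch within trial), all regressors z-scored so
that coefficients are standardized effect sizes in seconds per z-unit.
Group comparisons use a two-way mixed-design ANOVA (treatment group
between-subject, visit within-subject), two-sample t-tests, and label
permutation tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionResult",
    "GroupTestResult",
    "fit_duration_regressions",
    "effort_incentive_correlation",
    "mixed_anova",
    "permutation_test",
    "two_proportion_ztest",
    "REGRESSORS",
]

#: Regressor columns used by the duration regressions, in design order.
REGRESSORS = ("incentive", "difficulty", "block", "trial", "epoch_index")


@dataclass
class RegressionResult:
    """OLS coefficients (s per z-unit) for one subject-visit and epoch kind."""

    kind: str                     # "effort" or "rest"
    intercept: float              # mean duration, s (balanced design)
    coefficients: dict            # regressor -> beta
    condition_number: float
    n_epochs: int


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def fit_duration_regressions(
    epoch_table: pd.DataFrame,
    regressors=REGRESSORS,
) -> dict[str, RegressionResult]:
    """Multiple linear regression of epoch durations, per epoch kind.

    ``epoch_table`` needs columns ``duration``, ``kind`` ("effort"/"rest")
    and the regressor columns.  Regressors (except the constant) are
    z-scored.  A rank-deficient design raises an error naming the collinear
    columns.
    """
    import statsmodels.api as sm

    out = {}
    for kind, sub in epoch_table.groupby("kind"):
        cols = [r for r in regressors if sub[r].nunique() > 1]
        dropped = [r for r in regressors if r not in cols]
        if len(sub) < len(cols) + 2:
            raise ValueError(f"too few {kind} epochs for {len(cols)} regressors")
        X = np.column_stack([_zscore(sub[c].to_numpy(float)) for c in cols])
        Xc = sm.add_constant(X)
        rank = np.linalg.matrix_rank(Xc)
        if rank < Xc.shape[1]:
            corr = np.corrcoef(X, rowvar=False)
            np.fill_diagonal(corr, 0.0)
            i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
            raise ValueError(
                f"rank-deficient design for {kind}: collinear columns "
                f"{cols[i]!r} and {cols[j]!r}"
            )
        res = sm.OLS(sub["duration"].to_numpy(float), Xc).fit()
        coefs = dict(zip(cols, res.params[1:]))
        coefs.update({r: 0.0 for r in dropped})
        out[kind] = RegressionResult(
            kind=kind,
            intercept=float(res.params[0]),
            coefficients=coefs,
            condition_number=float(np.linalg.cond(Xc)),
            n_epochs=len(sub),
        )
    return out


def effort_incentive_correlation(subject_table: pd.DataFrame):
    """Across-subject Pearson correlation of mean effort duration with its
    incentive sensitivity.

    ``subject_table`` needs one row per subject with columns
    ``effort_mean`` and ``effort_incentive_beta`` (values averaged over
    visits beforehand).  Returns (rho, p).
    """
    if len(subject_table) < 3:
        raise ValueError("need at least 3 subjects")
    r, p = stats.pearsonr(
        subject_table["effort_mean"], subject_table["effort_incentive_beta"]
    )
    return float(r), float(p)


@dataclass
class GroupTestResult:
    """Outcome of a group-level test."""

    statistic: float
    df1: float
    df2: float
    p_value: float
    effect: str = ""
    n_permutations: int = 0


def mixed_anova(
    table: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    group: str = "group",
    within: str = "visit",
    engine: str = "classical",
):
    """Two-way mixed-design ANOVA: group between-subject, visit within.

    ``engine="classical"`` runs the standard mixed-design ANOVA (pingouin).
    ``engine="lmm"`` fits a random-intercept linear mixed model
    (statsmodels MixedLM) and reports Wald F statistics with
    between-within denominator degrees of freedom as an approximation to
    the Satterthwaite-corrected dfs of mixed-effects software.  The engine
    used is recorded on each result's ``effect`` tag.

    Requires complete cases per engine rules and at least 2 subjects per
    group.  Returns a dict effect name -> GroupTestResult for "group",
    "within" and "interaction".
    """
    counts = table.groupby(group)[subject].nunique()
    if (counts < 2).any():
        raise ValueError("each group needs at least 2 subjects")
    dup = table.groupby([subject, within])[dv].count()
    if (dup > 1).any():
        raise ValueError("at most one value per subject x visit")
    if np.ptp(table[dv].to_numpy(float)) == 0.0:
        # degenerate constant response: every F is 0/0, report null effects
        return {
            eff: GroupTestResult(statistic=0.0, df1=np.nan, df2=np.nan,
                                 p_value=1.0, effect=f"{eff} [degenerate]")
            for eff in ("group", "within", "interaction")
        }
    if engine == "classical":
        import pingouin as pg

        aov = pg.mixed_anova(
            data=table, dv=dv, within=within, between=group, subject=subject
        )
        mapping = {group: "group", within: "within", "Interaction": "interaction"}
        out = {}
        for _, row in aov.iterrows():
            name = mapping.get(row["Source"], row["Source"])
            out[name] = GroupTestResult(
                statistic=float(row["F"]),
                df1=float(row["DF1"]),
                df2=float(row["DF2"]),
                p_value=float(row["p_unc"]),
                effect=f"{name} [classical]",
            )
        return out
    elif engine == "lmm":
        import statsmodels.formula.api as smf

        df = table.rename(
            columns={dv: "_dv", subject: "_subj", group: "_grp", within: "_vis"}
        )
        # sum-to-zero contrasts so main-effect tests are Type-III-like
        model = smf.mixedlm(
            "_dv ~ C(_grp, Sum) * C(_vis, Sum)", df, groups=df["_subj"]
        )
        fit = model.fit(reml=True, method="lbfgs")
        terms = {"group": "C(_grp, Sum)", "within": "C(_vis, Sum)",
                 "interaction": ":"}
        names = np.asarray(fit.model.exog_names)
        n_sub = df["_subj"].nunique()
        n_obs = len(df)
        out = {}
        for eff, pat in terms.items():
            if eff == "interaction":
                idx = [i for i, nm in enumerate(names) if ":" in nm]
            else:
                idx = [i for i, nm in enumerate(names)
                       if nm.startswith(pat) and ":" not in nm]
            hyp = ", ".join(f"{names[i]} = 0" for i in idx)
            wald = fit.wald_test(hyp, scalar=True)
            df1 = len(idx)
            fstat = float(np.squeeze(wald.statistic)) / df1  # chi2 -> F scale
            df2 = float(n_sub - 2 if eff == "group" else n_obs - n_sub - df1)
            pval = float(stats.f.sf(fstat, df1, df2))
            out[eff] = GroupTestResult(
                statistic=fstat, df1=df1, df2=df2, p_value=pval,
                effect=f"{eff} [lmm]",
            )
        return out
    raise ValueError(f"unknown engine {engine!r}")


def permutation_test(
    values,
    labels,
    statistic=None,
    n_perm: int = 10000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> GroupTestResult:
    """Label-permutation test of a two-group statistic.

    ``statistic(values, labels)`` defaults to the difference of group
    means.  The p-value uses the add-one estimator
    ``p = (1 + #{permuted >= observed}) / (n_perm + 1)``; two-sided tests
    compare absolute values.  Seeded and deterministic.
    """
    import warnings

    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError("exactly two labels required")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p-value")
    if statistic is None:
        def statistic(v, l):
            return float(v[l == uniq[0]].mean() - v[l == uniq[1]].mean())

    obs = statistic(values, labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        s = statistic(values, perm)
        if alternative == "two-sided":
            count += abs(s) >= abs(obs)
        else:
            count += s >= obs
    p = (1 + count) / (n_perm + 1)
    return GroupTestResult(
        statistic=float(obs), df1=np.nan, df2=np.nan,
        p_value=float(p), effect="permutation", n_permutations=n_perm,
    )


def two_proportion_ztest(count1, n1, count2, n2):
    """Generic two-proportion z-test (pooled variance). Returns (z, p)."""
    p1, p2 = count1 / n1, count2 / n2
    pooled = (count1 + count2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))
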