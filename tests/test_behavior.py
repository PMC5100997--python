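"""Duration regressions, correlation and group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from effortalloc import (
    CohortSpec,
    ParameterSet,
    design_conditions,
    draw_parameters,
    effort_incentive_correlation,
    fit_duration_regressions,
    mixed_anova,
    permutation_test,
    predict_durations,
    simulate_condition_summaries,
)
from effortalloc.behavior import two_proportion_ztest


def _zs(x):
    x = np.asarray(x, float)
    return (x - x.mean()) / x.std(ddof=1)


def make_epoch_table(effect=None, noise=0.0, rng=None, n_epochs=3):
    """Balanced epoch table over 8 blocks x 9 conditions x n epochs."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for b in range(8):
        for ti, (inc, dif) in enumerate(
            [(i, d) for i in (1, 2, 5) for d in (0.7, 0.8, 0.9)]
        ):
            for e in range(n_epochs):
                for kind in ("effort", "rest"):
                    rows.append(
                        dict(duration=0.0, kind=kind, incentive=inc,
                             difficulty=dif, block=b, trial=ti, epoch_index=e)
                    )
    df = pd.DataFrame(rows)
    for kind in ("effort", "rest"):
        m = df["kind"] == kind
        base = 5.0 if kind == "effort" else 3.0
        y = np.full(m.sum(), base)
        if effect:
            for col, beta in effect.get(kind, {}).items():
                y = y + beta * _zs(df.loc[m, col])
        y = y + rng.normal(0, noise, y.size)
        df.loc[m, "duration"] = y
    return df


class TestDurationRegressions:
    def test_planted_incentive_effect_recovered_exactly(self):
        df = make_epoch_table(effect={"effort": {"incentive": 2.0}})
        res = fit_duration_regressions(df)
        assert res["effort"].coefficients["incentive"] == pytest.approx(2.0)
        assert res["effort"].intercept == pytest.approx(5.0)

    def test_constant_durations_give_zero_betas(self):
        df = make_epoch_table()
        res = fit_duration_regressions(df)
        for kind in ("effort", "rest"):
            for v in res[kind].coefficients.values():
                assert abs(v) < 1e-10
            assert res[kind].intercept == pytest.approx(
                5.0 if kind == "effort" else 3.0
            )

    def test_multi_factor_recovery_matches_normal_equations(self):
        truth = {"effort": {"incentive": 1.5, "difficulty": -0.8, "block": 0.3}}
        rng = np.random.default_rng(7)
        df = make_epoch_table(effect=truth, noise=0.5, rng=rng)
        res = fit_duration_regressions(df)
        # independent oracle: solve the normal equations directly
        sub = df[df["kind"] == "effort"]
        X = np.column_stack(
            [np.ones(len(sub))]
            + [_zs(sub[c]) for c in
               ("incentive", "difficulty", "block", "trial", "epoch_index")]
        )
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ sub["duration"].to_numpy())
        assert res["effort"].intercept == pytest.approx(beta_oracle[0], abs=1e-9)
        assert res["effort"].coefficients["incentive"] == pytest.approx(
            beta_oracle[1], abs=1e-9
        )
        # and the estimates sit near the planted truth
        sigma2 = 0.25
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert abs(res["effort"].coefficients["incentive"] - 1.5) < 3 * se

    def test_intercept_equals_mean_duration_in_balanced_design(self):
        rng = np.random.default_rng(11)
        df = make_epoch_table(effect={"effort": {"incentive": 1.0}},
                              noise=0.3, rng=rng)
        res = fit_duration_regressions(df)
        mean_eff = df.loc[df["kind"] == "effort", "duration"].mean()
        assert res["effort"].intercept == pytest.approx(mean_eff, abs=1e-9)

    def test_collinear_design_errors_with_names(self):
        df = make_epoch_table()
        df["difficulty"] = df["incentive"] * 2.0
        with pytest.raises(ValueError, match="incentive.*difficulty"):
            fit_duration_regressions(df)


class TestEffortIncentiveCorrelation:
    def test_proportional_columns_give_unit_correlation(self):
        t = pd.DataFrame(
            {"effort_mean": [1.0, 2, 3, 4], "effort_incentive_beta": [3.0, 6, 9, 12]}
        )
        rho, p = effort_incentive_correlation(t)
        assert rho == pytest.approx(1.0)

    def test_too_few_subjects_error(self):
        t = pd.DataFrame({"effort_mean": [1, 2], "effort_incentive_beta": [1, 2]})
        with pytest.raises(ValueError):
            effort_incentive_correlation(t)

    def test_sem_heterogeneity_induces_positive_correlation(self):
        """Model prediction: when only the mean accumulation slope varies
        across subjects, longer mean effort goes with larger incentive
        sensitivity."""
        pop = {"Sem": (0.16, 0.05), "Srm": (0.37, 0.0), "Ai": (0.15, 0.0),
               "Sed": (0.021, 0.0), "Sri": (0.086, 0.0)}
        params = draw_parameters(CohortSpec(population=pop, n_subjects=25, seed=13))
        conds = design_conditions()
        Ivals = np.array([c.I for c in conds])
        rows = []
        for i, ps in enumerate(params):
            s = simulate_condition_summaries(ps, rng=1000 + i)
            sens = np.polyfit(Ivals, s.te, 1)[0]
            rows.append({"effort_mean": s.te.mean(), "effort_incentive_beta": sens})
        rho, p = effort_incentive_correlation(pd.DataFrame(rows))
        assert rho > 0.5 and p < 0.01


def make_anova_table(shift=0.0, noise=0.5, n_per_group=12, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, gshift in (("placebo", 0.0), ("escitalopram", shift)):
        for s in range(n_per_group):
            base = rng.normal(5.0, 1.0)
            for v in ("initial", "intermediate", "late"):
                rows.append(
                    dict(subject=f"{g}{s}", group=g, visit=v,
                         value=base + gshift + rng.normal(0, noise))
                )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_identical_groups_zero_noise_give_null_f(self):
        rows = []
        for g in ("a", "b"):
            for s in range(5):
                for v in range(3):
                    rows.append(dict(subject=f"{g}{s}", group=g, visit=v, value=4.2))
        res = mixed_anova(pd.DataFrame(rows))
        assert res["group"].statistic == pytest.approx(0.0, abs=1e-9)

    def test_matches_hand_computed_sums_of_squares(self):
        """Cross-implementation oracle: classical mixed-design F for the
        between factor computed from scratch on a balanced table."""
        t = make_anova_table(shift=1.0, seed=3)
        res = mixed_anova(t)
        # oracle: between-subjects ANOVA on subject means
        subj = t.groupby(["subject", "group"], as_index=False)["value"].mean()
        k = t["visit"].nunique()
        grand = subj["value"].mean()
        groups = [g["value"].to_numpy() for _, g in subj.groupby("group")]
        ss_between = k * sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within_subj = k * sum(((g - g.mean()) ** 2).sum() for g in groups)
        df1 = len(groups) - 1
        df2 = sum(len(g) for g in groups) - len(groups)
        f_oracle = (ss_between / df1) / (ss_within_subj / df2)
        assert res["group"].statistic == pytest.approx(f_oracle, abs=1e-6)
        assert res["group"].df1 == df1 and res["group"].df2 == df2

    def test_engines_agree_on_balanced_group_effect(self):
        t = make_anova_table(shift=0.8, seed=5)
        f1 = mixed_anova(t)["group"].statistic
        f2 = mixed_anova(t, engine="lmm")["group"].statistic
        assert f1 == pytest.approx(f2, rel=1e-4)

    def test_type_one_error_calibrated(self):
        """Null simulations reject at close to the nominal 5% rate."""
        n_rej = 0
        n_rep = 200
        for i in range(n_rep):
            t = make_anova_table(shift=0.0, n_per_group=8, seed=1000 + i)
            if mixed_anova(t)["group"].p_value < 0.05:
                n_rej += 1
        rate = n_rej / n_rep
        assert 0.01 <= rate <= 0.10   # 3 binomial sd around 0.05

    def test_single_subject_group_errors(self):
        t = make_anova_table(n_per_group=4)
        t = t[~((t.group == "placebo") & (t.subject != "placebo0"))]
        with pytest.raises(ValueError, match="at least 2 subjects"):
            mixed_anova(t)


class TestPermutationTest:
    def test_label_invariant_statistic_gives_p_one(self):
        vals = np.ones(20)
        labs = np.array(["a"] * 10 + ["b"] * 10)
        res = permutation_test(vals, labs, n_perm=500, seed=0)
        assert res.p_value == pytest.approx(1.0)

    def test_huge_separation_gives_minimal_p(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(0, 1, 29), rng.normal(10, 1, 29)])
        labs = np.array(["a"] * 29 + ["b"] * 29)
        res = permutation_test(vals, labs, n_perm=2000, seed=1)
        assert res.p_value == pytest.approx(1 / 2001, abs=1e-12)

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, 30)
        labs = np.array(["a", "b"] * 15)
        p1 = permutation_test(vals, labs, n_perm=500, seed=5).p_value
        p2 = permutation_test(vals, labs, n_perm=500, seed=5).p_value
        assert p1 == p2

    def test_agrees_with_t_test_order_of_magnitude(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(0, 1, 25), rng.normal(0.9, 1, 25)])
        labs = np.array(["a"] * 25 + ["b"] * 25)
        p_perm = permutation_test(vals, labs, n_perm=5000, seed=0).p_value
        p_t = stats.ttest_ind(vals[:25], vals[25:]).pvalue
        assert abs(np.log10(p_perm) - np.log10(p_t)) < 1.0

    def test_scale_invariance_of_group_contrast(self):
        """Affine rescaling applied to both groups (e.g. a different payoff
        constant) leaves the permutation p unchanged."""
        rng = np.random.default_rng(4)
        vals = rng.normal(5, 2, 40)
        labs = np.array(["a", "b"] * 20)
        p1 = permutation_test(vals, labs, n_perm=1000, seed=9).p_value
        p2 = permutation_test(3.7 * vals + 11, labs, n_perm=1000, seed=9).p_value
        assert p1 == p2


def test_two_proportion_ztest_basic():
    z, p = two_proportion_ztest(16, 29, 13, 29)
    assert p > 0.05
    z2, p2 = two_proportion_ztest(25, 29, 5, 29)
    assert p2 < 0.001
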