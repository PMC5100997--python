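"""Forward model, design covariates and model-space enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from effortalloc import (
    BEST_MODEL,
    Condition,
    ModelSpec,
    ParameterSet,
    cost_evidence_trajectory,
    design_conditions,
    enumerate_model_space,
    enumerate_unconstrained_space,
    predict_durations,
    zscore_levels,
)


class TestZscoreLevels:
    def test_task_incentive_levels(self):
        np.testing.assert_allclose(
            zscore_levels([1, 2, 5]), [-0.801, -0.320, 1.121], atol=1e-3
        )

    def test_symmetric_difficulty_levels(self):
        np.testing.assert_allclose(zscore_levels([70, 80, 90]), [-1, 0, 1], atol=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            zscore_levels([5, 5, 5])

    @given(
        st.lists(
            st.floats(-1e3, 1e3, allow_nan=False), min_size=2, max_size=10
        ).filter(lambda xs: max(xs) - min(xs) > 1e-6)
    )
    @settings(deadline=None, max_examples=50)
    def test_normalization_invariant(self, xs):
        z = zscore_levels(xs)
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1) < 1e-9


class TestPredictDurations:
    def test_placebo_baseline_durations(self, placebo_truth):
        # at I = D = 0 the means are simply 1/Sem and 1/Srm
        pred = predict_durations(
            ParameterSet(Sem=0.16, Srm=0.37), Condition(2, 0.80)
        )
        assert pred.Te == pytest.approx(6.25, abs=1e-9)
        assert pred.Tr == pytest.approx(2.7027, abs=1e-4)

    def test_incentive_modulated_effort(self):
        # A = 1 + 0.15 * 1.120..., Se = 0.16
        p = ParameterSet(Sem=0.16, Srm=0.37, Ai=0.15)
        cond = Condition(5, 0.80)
        assert predict_durations(p, cond).Te == pytest.approx(
            (1 + 0.15 * cond.I) / 0.16, rel=1e-12
        )
        assert predict_durations(p, cond).Te == pytest.approx(7.30, abs=0.005)

    def test_scale_invariance(self, rng):
        """(A, Se, Sr) jointly rescaled leave durations unchanged."""
        for _ in range(20):
            sem, srm = rng.uniform(0.05, 0.5, 2)
            ai = rng.uniform(-0.2, 0.5)
            c = rng.uniform(0.1, 10.0)
            cond = Condition(5, 0.70)
            p1 = ParameterSet(Sem=sem, Srm=srm, Ai=ai)
            p2 = ParameterSet(Sem=c * sem, Srm=c * srm, Ai=c * ai, Am=c)
            d1, d2 = predict_durations(p1, cond), predict_durations(p2, cond)
            assert d1.Te == pytest.approx(d2.Te, rel=1e-12)
            assert d1.Tr == pytest.approx(d2.Tr, rel=1e-12)

    def test_invalid_parameters_error(self):
        p = ParameterSet(Sem=0.02, Srm=0.37, Sed=0.05)  # Se < 0 at D = -1
        with pytest.raises(ValueError, match="non-positive"):
            predict_durations(p, Condition(2, 0.70))

    def test_qualitative_task_effects(self, placebo_truth):
        """Te rises with incentive, falls with difficulty; Tr falls with incentive."""
        te = {}
        tr = {}
        for i in (1, 2, 5):
            d = predict_durations(placebo_truth, Condition(i, 0.80))
            te[i], tr[i] = d.Te, d.Tr
        assert te[1] < te[2] < te[5]
        assert tr[1] > tr[2] > tr[5]
        te_d = [
            predict_durations(placebo_truth, Condition(2, d)).Te
            for d in (0.70, 0.80, 0.90)
        ]
        assert te_d[0] > te_d[1] > te_d[2]

    def test_effort_duration_couples_with_incentive_sensitivity(self, rng):
        """Lower mean accumulation slope implies both longer effort and a
        larger effect of incentive on effort duration (dTe/dI = Ai/Se)."""
        sems = np.linspace(0.08, 0.3, 15)
        conds = [Condition(i, 0.80) for i in (1, 2, 5)]
        means, sens = [], []
        for sem in sems:
            p = ParameterSet(Sem=sem, Srm=0.37, Ai=0.15)
            te = [predict_durations(p, c).Te for c in conds]
            means.append(np.mean(te))
            sens.append(np.polyfit([c.I for c in conds], te, 1)[0])
        # analytic: sensitivity = Ai / Sem at D = 0
        np.testing.assert_allclose(sens, 0.15 / sems, rtol=1e-9)
        from scipy.stats import spearmanr

        assert spearmanr(means, sens).statistic > 0.99


class TestModelSpace:
    def test_twenty_admissible_of_sixtyfour(self):
        space = enumerate_model_space()
        full = enumerate_unconstrained_space()
        assert len(space) == 20
        assert len(full) == 64
        assert len(set(space)) == 20
        assert set(space) <= set(full)

    def test_contains_best_model_excludes_lone_Ad(self):
        space = enumerate_model_space()
        assert BEST_MODEL in space
        assert ModelSpec(has_Ad=True) not in space
        assert ModelSpec(has_Srd=True) not in space

    def test_deterministic_order(self):
        assert [m.name for m in enumerate_model_space()] == [
            m.name for m in enumerate_model_space()
        ]

    def test_every_member_can_produce_the_three_task_effects(self):
        """Each admissible model admits a parameterization producing all
        three qualitative effects: Te up with incentive, Tr down with
        incentive, Te down with difficulty.  Checked by a small sign/
        magnitude search over the active modulations."""
        import itertools

        conds_i = [Condition(i, 0.80) for i in (1, 2, 5)]
        conds_d = [Condition(2, d) for d in (0.70, 0.80, 0.90)]

        def produces_effects(p):
            try:
                te_i = [predict_durations(p, c).Te for c in conds_i]
                tr_i = [predict_durations(p, c).Tr for c in conds_i]
                te_d = [predict_durations(p, c).Te for c in conds_d]
            except ValueError:
                return False
            return (
                all(np.diff(te_i) > 0)
                and all(np.diff(tr_i) < 0)
                and all(np.diff(te_d) < 0)
            )

        for spec in enumerate_model_space():
            found = False
            for signs in itertools.product((-0.08, 0.08), repeat=len(spec.active)):
                p = ParameterSet(Sem=0.2, Srm=0.4, **dict(zip(spec.active, signs)))
                if produces_effects(p):
                    found = True
                    break
            assert found, f"{spec.name} cannot produce the three task effects"

    def test_name_round_trip(self):
        for spec in enumerate_model_space():
            assert ModelSpec.from_name(spec.name) == spec
        assert ModelSpec.from_name("null") == ModelSpec()


class TestTrajectory:
    def test_epoch_schedule_at_placebo_means(self):
        p = ParameterSet(Sem=0.16, Srm=0.37)
        _, _, epochs = cost_evidence_trajectory(p, Condition(2, 0.80), 30.0)
        eff = [(on, off) for on, off, kind, _ in epochs if kind == "effort"]
        expected = [(0.0, 6.25), (8.95, 15.20), (17.91, 24.16), (26.86, 30.0)]
        for (on, off), (eon, eoff) in zip(eff, expected):
            assert on == pytest.approx(eon, abs=0.01)
            assert off == pytest.approx(eoff, abs=0.01)
        assert epochs[-1][3]  # final epoch truncated

    def test_short_trial_truncates_first_effort(self):
        p = ParameterSet(Sem=0.16, Srm=0.37)  # Te = 6.25
        _, _, epochs = cost_evidence_trajectory(p, Condition(2, 0.80), 3.0)
        assert len(epochs) == 1
        on, off, kind, trunc = epochs[0]
        assert kind == "effort" and trunc and off == 3.0

    def test_extrema_alternate_between_bounds(self):
        p = ParameterSet(Sem=0.3, Srm=0.5, Ai=0.1)
        cond = Condition(5, 0.90)
        A = 1 + 0.1 * cond.I
        t, v, epochs = cost_evidence_trajectory(p, cond, 30.0)
        interior = v[:-1] if epochs[-1][3] else v
        for x in interior:
            assert min(abs(x - 0.0), abs(x - A)) < 1e-9

    def test_initial_latency_prepends_rest(self):
        p = ParameterSet(Sem=0.16, Srm=0.37)
        _, _, epochs = cost_evidence_trajectory(
            p, Condition(2, 0.80), 30.0, initial_latency=2.0
        )
        assert epochs[0][:3] == (0.0, 2.0, "rest")
        assert epochs[1][0] == 2.0 and epochs[1][2] == "effort"
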