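"""Microsimulation engine: transitions, identities, and both code paths."""

import numpy as np
import pytest

from oacbenefit.engine import (
    PatientState,
    build_cycle_plan,
    simulate_arm,
    simulate_arm_reference,
)
from oacbenefit.params import annual_to_monthly


class TestCyclePlan:
    def test_untreated_stroke_probability(self, params):
        p = PatientState(arm="none", age=70.0)
        plan = build_cycle_plan(p, params, risk=0.06)
        assert plan.p_ischemic_stroke == pytest.approx(
            annual_to_monthly(0.06), abs=1e-12)
        assert not plan.doac_active

    def test_doac_stroke_probability_carries_relative_risk(self, params):
        p = PatientState(arm="doac", age=70.0)
        plan = build_cycle_plan(p, params, risk=0.06)
        assert plan.p_ischemic_stroke == pytest.approx(
            annual_to_monthly(0.06 * 0.32), abs=1e-12)  # ~0.001615
        assert plan.p_extracranial_bleed == pytest.approx(
            annual_to_monthly(0.022 * 1.91 * 0.82), abs=1e-12)

    def test_paused_patient_uses_untreated_effects(self, params):
        paused = PatientState(arm="doac", doac_pause_remaining=1, age=70.0)
        untreated = PatientState(arm="none", age=70.0)
        pp = build_cycle_plan(paused, params, risk=0.03)
        up = build_cycle_plan(untreated, params, risk=0.03)
        assert pp.as_array() == pytest.approx(up.as_array(), abs=1e-15)

    def test_post_event_window_elevates_mortality(self, params):
        recent = PatientState(arm="none", window_type=1,
                              months_since_event=3, age=70.0)
        plan = build_cycle_plan(recent, params, risk=0.01)
        assert plan.p_other_cause_death == pytest.approx(
            annual_to_monthly(0.14), abs=1e-12)
        # after the 12-cycle window, back to baseline
        late = PatientState(arm="none", window_type=1,
                            months_since_event=12, age=70.0)
        plan = build_cycle_plan(late, params, risk=0.01)
        assert plan.p_other_cause_death == pytest.approx(
            annual_to_monthly(0.037), abs=1e-12)

    def test_dead_patient_has_no_plan(self, params):
        dead = PatientState(arm="none", alive=False)
        with pytest.raises(ValueError):
            build_cycle_plan(dead, params, risk=0.01)


class TestVectorizedAgainstScalarReference:
    @pytest.mark.parametrize("arm", ["doac", "none"])
    def test_exact_agreement_given_shared_uniforms(self, params, arm):
        rng = np.random.default_rng(1234)
        uniforms = rng.random((72, 2, 60))
        fast = simulate_arm(0.05, arm, params, n=60, horizon_months=72,
                            uniforms=uniforms)
        slow = simulate_arm_reference(0.05, arm, params, uniforms=uniforms)
        np.testing.assert_allclose(fast.qalys, slow.qalys, atol=1e-12)
        np.testing.assert_allclose(fast.disability_free_years,
                                   slow.disability_free_years, atol=1e-12)
        assert fast.event_counts == slow.event_counts
        assert fast.deaths == slow.deaths


class TestIdentities:
    def test_zero_event_closed_form(self, zero_event):
        res = simulate_arm(0.0, "none", zero_event, n=50, seed=0)
        table = zero_event.utilities
        expected = sum(
            table.baseline(70 + t / 12.0) / 12.0 for t in range(240)
        )
        np.testing.assert_allclose(res.qalys, expected, atol=1e-9)
        np.testing.assert_allclose(res.disability_free_years, 20.0, atol=1e-12)
        assert res.deaths == 0

    def test_zero_event_arms_identical(self, zero_event):
        d = simulate_arm(0.0, "doac", zero_event, n=100, seed=3)
        n = simulate_arm(0.0, "none", zero_event, n=100, seed=3)
        np.testing.assert_array_equal(d.qalys, n.qalys)

    def test_certain_death_first_cycle(self, certain_death):
        res = simulate_arm(0.0, "none", certain_death, n=50, seed=0)
        assert res.deaths == 50
        np.testing.assert_array_equal(res.qalys, 0.0)
        np.testing.assert_array_equal(res.disability_free_years, 0.0)

    def test_no_effect_arms_identical_under_common_random_numbers(self, no_effect):
        d = simulate_arm(0.03, "doac", no_effect, n=500, horizon_months=120, seed=7)
        n = simulate_arm(0.03, "none", no_effect, n=500, horizon_months=120, seed=7)
        np.testing.assert_array_equal(d.qalys, n.qalys)
        np.testing.assert_array_equal(d.disability_free_years,
                                      n.disability_free_years)

    def test_determinism_under_seed(self, params):
        a = simulate_arm(0.02, "doac", params, n=200, horizon_months=60, seed=42)
        b = simulate_arm(0.02, "doac", params, n=200, horizon_months=60, seed=42)
        np.testing.assert_array_equal(a.qalys, b.qalys)
        assert a.event_counts == b.event_counts


class TestDynamics:
    def test_first_year_stroke_incidence_matches_input_rate(self, params):
        n = 40_000
        res = simulate_arm(0.06, "none", params, n=n, horizon_months=12, seed=5)
        incidence = res.event_counts["ischemic_stroke"] / n
        # slightly below 6% because death and bleeds compete within a year
        assert incidence == pytest.approx(0.059, abs=0.004)

    def test_mean_qalys_decrease_with_risk(self, params):
        means = [
            simulate_arm(r, arm, params, n=4000, seed=11).mean_qalys
            for arm in ("doac", "none")
            for r in (0.01, 0.03, 0.06, 0.09)
        ]
        doac, none = means[:4], means[4:]
        assert all(np.diff(doac) < 0)
        assert all(np.diff(none) < 0)

    def test_harmful_treatment_is_strictly_worse(self, params):
        import copy
        from oacbenefit.params import EffectAnchors
        harm = copy.deepcopy(params)
        harm.stroke_effect = EffectAnchors(0.01, 0.0, 0.06, 0.0)
        harm.mortality_effect = EffectAnchors(0.01, 0.0, 0.06, 0.0,
                                              floor_below_lower=True)
        harm.bleed_relative_risk = 8.0
        harm.validate()
        d = simulate_arm(0.02, "doac", harm, n=4000, seed=9)
        n = simulate_arm(0.02, "none", harm, n=4000, seed=9)
        assert d.mean_qalys < n.mean_qalys

    def test_qalys_bounded_by_horizon(self, params):
        res = simulate_arm(0.02, "none", params, n=1000, seed=1)
        max_w = max(params.utilities.baseline_by_age_band.values())
        assert res.qalys.max() <= 20.0 * max_w + 1e-9
        assert res.disability_free_years.max() <= 20.0 + 1e-12
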