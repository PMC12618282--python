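"""Markov engine: transitions, discounting, traces, and oracle equivalence.

The reference implementation below re-derives the cohort recursion with
plain scalar arithmetic (no shared code with the engine beyond schedule
lookups) and serves as the independent oracle for run_cohort.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cariescea.interventions import builtin_intervention
from cariescea.markov_engine import (
    EngineError,
    HealthState,
    discount,
    run_cohort,
    transition_step,
)

from conftest import small_config

SETTINGS = dict(deadline=None, max_examples=100, derandomize=True)


# ---------------------------------------------------------------------------
# Independent scalar reference
# ---------------------------------------------------------------------------

def reference_run(config, intervention=None):
    """Loop-based scalar re-derivation of one arm's totals."""
    v, c = config.valuation, config.costs
    sf = v.symptomatic_fraction_value
    yld = v.disability_weight * sf * v.episode_duration_days / 365.0
    qal = ((1.0 - v.baseline_utility) / 2.0) * sf * v.episode_duration_days / 365.0
    treat = c.treatment_access_prob * (
        c.checkup_fee + v.teeth_per_case * c.restoration_fee_per_tooth)
    r = config.econ.discount_rate_per_year
    out = {k: 0.0 for k in ("cases", "dt", "hc", "ic", "daly", "qaly",
                            "dt_disc", "cost_disc")}
    for a0, n0 in config.cohort.subcohorts():
        cf, ca = n0, 0.0
        for t in range(config.horizon_years):
            age = a0 + t
            total = config.incidence.rate_at(age)
            share = config.incidence.deciduous_share_at(age)
            dec, perm = total * share, total * (1.0 - share)
            if intervention is not None and t < intervention.effect_window_years:
                if intervention.id in ("1a", "1b"):
                    red = -intervention.delta_dmft / v.teeth_per_case \
                        / intervention.effect_window_years
                    dec = max(0.0, dec - red)
                elif intervention.id in ("2a", "2b"):
                    dec *= 1.0 - intervention.pf_deciduous
                    perm *= 1.0 - intervention.pf_permanent
                else:  # sealants: odds ratio on the occlusal-molar share
                    s = config.incidence.occlusal_molar_share
                    occ = perm * s
                    o = intervention.odds_ratio
                    perm = (perm - occ) + o * occ / (1.0 - occ + o * occ)
            m = config.mortality.rate_at(age)
            cases = cf * (1.0 - m) * (dec + perm)
            ic = 0.0
            if intervention is not None and t < len(intervention.visits_per_year):
                fee = sum(getattr(c, name)
                          for name in intervention.fee_components_per_visit)
                fee *= intervention.fee_units_per_visit
                if intervention.apply_stepdown:
                    fee *= c.stepdown_factor
                ic = intervention.visits_per_year[t] * fee * n0
                if t == 0 and intervention.includes_screening_first_visit:
                    ic += c.screening_fee * n0
            d = 1.0 / (1.0 + r) ** t
            out["cases"] += cases
            out["dt"] += cases * v.teeth_per_case
            out["hc"] += cases * treat
            out["ic"] += ic
            out["daly"] += cases * yld
            out["qaly"] += cases * qal
            out["dt_disc"] += cases * v.teeth_per_case * d
            out["cost_disc"] += (cases * treat + ic) * d
            new_cf = cf * (1.0 - m) * (1.0 - dec - perm) + ca * (1.0 - m)
            ca = cf * (1.0 - m) * (dec + perm)
            cf = new_cf
    return out


def engine_totals(trace):
    return {
        "cases": trace.cases.sum(),
        "dt": trace.decayed_teeth.sum(),
        "hc": trace.cost_healthcare.sum(),
        "ic": trace.cost_intervention.sum(),
        "daly": trace.dalys.sum(),
        "qaly": trace.qalys.sum(),
        "dt_disc": trace.decayed_teeth_disc.sum(),
        "cost_disc": trace.cost_total_disc.sum(),
    }


class TestDiscount:
    @pytest.mark.parametrize("amount, cycle, rate, expected", [
        (100.0, 0, 0.03, 100.0),
        (100.0, 2, 0.0, 100.0),
        (100.0, 2, 0.03, 94.2596),
    ])
    def test_values(self, amount, cycle, rate, expected):
        assert discount(amount, cycle, rate) == pytest.approx(expected, abs=1e-4)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            discount(100.0, 1, -0.01)
        with pytest.raises(ValueError, match="cycle_index"):
            discount(100.0, -1, 0.03)


class TestTransitionStep:
    def test_dead_is_absorbing(self):
        occ = np.array([0.0, 0.0, 0.0, 500.0])
        np.testing.assert_array_equal(
            transition_step(occ, 6.0, 0.3, 0.1, 0.5), occ)

    def test_zero_rates_identity(self):
        occ = np.array([700.0, 200.0, 0.0, 100.0])
        out = transition_step(occ, 6.0, 0.0, 0.0, 0.0)
        # caries mass recovers to caries-free but nothing else moves
        assert out[HealthState.DEAD] == 100.0
        assert out.sum() == pytest.approx(1000.0)

    def test_single_step_hand_oracle(self):
        # 1000 caries-free, incidence 0.2, mortality 0.01:
        # survivors 990, new cases 198, deaths 10
        out = transition_step(np.array([1000.0, 0.0, 0.0, 0.0]), 6.0,
                              0.15, 0.05, 0.01)
        np.testing.assert_allclose(out, [792.0, 198.0, 0.0, 10.0], rtol=1e-12)

    def test_absorbing_policy_keeps_cases(self):
        out = transition_step(np.array([0.0, 100.0, 0.0, 0.0]), 6.0, 0.2, 0.0,
                              0.0, recovery_rule="absorbing")
        assert out[HealthState.CARIES] == 100.0

    def test_negative_occupancy_rejected(self):
        with pytest.raises(EngineError, match="negative occupancy"):
            transition_step(np.array([-1.0, 0.0, 0.0, 0.0]), 6.0, 0.1, 0.0, 0.0)

    @given(cf=st.floats(0, 1e6), ca=st.floats(0, 1e6), ed=st.floats(0, 1e6),
           de=st.floats(0, 1e6), dec=st.floats(0, 0.5), perm=st.floats(0, 0.5),
           m=st.floats(0, 1), rule=st.sampled_from(["one_cycle", "absorbing"]))
    @settings(**SETTINGS)
    def test_mass_conserved_and_dead_monotone(self, cf, ca, ed, de, dec, perm,
                                              m, rule):
        occ = np.array([cf, ca, ed, de])
        out = transition_step(occ, 8.0, dec, perm, m, recovery_rule=rule)
        assert out.sum() == pytest.approx(occ.sum(), rel=1e-12, abs=1e-9)
        assert out[HealthState.DEAD] >= de
        assert np.all(out >= 0.0)


class TestRunCohort:
    def test_zero_incidence_zero_cases_and_costs(self):
        cfg = small_config(incidence_rate=0.0)
        tr = run_cohort(cfg)
        assert tr.cases.sum() == 0.0
        assert tr.cost_healthcare.sum() == 0.0
        assert tr.dalys.sum() == 0.0

    def test_mass_conserved_every_cycle(self, config_2a):
        tr = run_cohort(config_2a)
        size = config_2a.cohort.size_low_income
        np.testing.assert_allclose(tr.occupancy.sum(axis=1),
                                   np.full(tr.horizon + 1, size), rtol=1e-12)

    def test_null_intervention_equals_comparator(self):
        from cariescea.interventions import EffectKind, InterventionSpec
        null = InterventionSpec(
            id="2b", label="null", effect_kind=EffectKind.PREVENTIVE_FRACTION,
            effect_window_years=2, target_dentition="both",
            visits_per_year=(0, 0), fee_components_per_visit=(),
            pf_deciduous=0.0, pf_permanent=0.0)
        cfg = small_config()
        comp, arm = run_cohort(cfg), run_cohort(cfg, null)
        np.testing.assert_array_equal(comp.cases, arm.cases)
        np.testing.assert_array_equal(comp.cost_total, arm.cost_total)

    def test_comparator_invariant_to_other_runs(self, config_2a):
        before = run_cohort(config_2a)
        run_cohort(config_2a, builtin_intervention("2a"))
        after = run_cohort(config_2a)
        np.testing.assert_array_equal(before.occupancy, after.occupancy)
        np.testing.assert_array_equal(before.decayed_teeth, after.decayed_teeth)

    @pytest.mark.parametrize("iid, start_age, horizon",
                             [(None, 6.0, 6), ("2a", 7.0, 2), ("2b", 9.0, 2),
                              ("3", 12.0, 2), ("1a", 0.5, 6), ("1b", 0.5, 6)])
    def test_matches_scalar_reference(self, iid, start_age, horizon):
        cfg = small_config(start_age=start_age, size=1000, horizon=horizon,
                           incidence_rate=0.18, mortality_rate=0.003)
        spec = builtin_intervention(iid) if iid else None
        got = engine_totals(run_cohort(cfg, spec))
        want = reference_run(cfg, spec)
        for key in want:
            assert got[key] == pytest.approx(want[key], rel=1e-9), key

    def test_matches_reference_on_builtin_schedules(self, config_2a):
        got = engine_totals(run_cohort(config_2a, builtin_intervention("2a")))
        want = reference_run(config_2a, builtin_intervention("2a"))
        for key in want:
            assert got[key] == pytest.approx(want[key], rel=1e-9), key

    def test_discounted_never_exceeds_undiscounted(self, config_2a):
        tr = run_cohort(config_2a, builtin_intervention("2a"))
        assert tr.cost_total_disc.sum() <= tr.cost_total.sum()
        assert tr.decayed_teeth_disc.sum() <= tr.decayed_teeth.sum()
        assert tr.dalys_disc.sum() <= tr.dalys.sum()

    def test_silent_tail_leaves_totals_unchanged(self):
        # zero rates from age 6: extending the horizon 6 -> 12 adds nothing
        import dataclasses
        cfg6 = small_config(start_age=0.5, horizon=6, incidence_rate=0.2,
                            mortality_rate=0.0)
        inc = cfg6.incidence
        zeroed = dataclasses.replace(
            inc, general=np.where(inc.ages >= 6, 0.0, inc.general),
            low_income=np.where(inc.ages >= 6, 0.0, inc.low_income))
        cfg6 = dataclasses.replace(cfg6, incidence=zeroed)
        cfg12 = dataclasses.replace(cfg6, horizon_years=12)
        spec = builtin_intervention("1a")
        for s in (None, spec):
            a = engine_totals(run_cohort(cfg6, s))
            b = engine_totals(run_cohort(cfg12, s))
            for key in a:
                assert b[key] == pytest.approx(a[key], rel=1e-12), key

    def test_effect_window_must_fit_horizon(self):
        cfg = small_config(horizon=2)
        with pytest.raises(ValueError, match="effect window"):
            run_cohort(cfg, builtin_intervention("1a"))

    def test_trace_frame_and_addition(self, config_2a):
        tr = run_cohort(config_2a)
        df = tr.to_frame()
        assert len(df) == config_2a.horizon_years
        assert {"cycle", "caries_free", "cases_deciduous", "dalys_disc"} <= set(df.columns)
        double = tr + tr
        np.testing.assert_allclose(double.decayed_teeth, 2 * tr.decayed_teeth)

    def test_half_cycle_person_years_between_bounds(self):
        cfg = small_config(mortality_rate=0.2, incidence_rate=0.0)
        tr = run_cohort(cfg)
        start = tr.occupancy[:-1, :3].sum(axis=1)
        end = tr.occupancy[1:, :3].sum(axis=1)
        assert np.all(tr.person_years <= start) and np.all(tr.person_years >= end)
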