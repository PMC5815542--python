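"""Markov engine: branch probabilities, mortality adjustment, transition
matrix structure and cohort propagation, validated against independent
enumeration and survival-product oracles and a per-patient microsimulation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cathcea.economics import accumulate
from cathcea.lifetable import LifeTable, annual_to_monthly_prob
from cathcea.markov import (
    ARMS,
    DEAD,
    EVENT_TYPES,
    N_STATES,
    ModelParameters,
    RenalStage,
    UtiLevel,
    adjusted_death_prob,
    apply_treatment_effect,
    arm_event_probs,
    build_transition_matrix,
    run_cohort,
    state_index,
    uti_branch_probs,
    weighted_uti_multiplier,
)
from cathcea.validation import microsim

probs01 = st.floats(min_value=0.0, max_value=1.0)


def zeroed(params: ModelParameters) -> ModelParameters:
    """All disease parameters off: pure background mortality."""
    return params.with_overrides(
        p_uti_pvc=0.0,
        overlay_event_probs={k: 0.0 for k in params.overlay_event_probs},
        p_progress_significant=0.0,
        p_progress_failure=0.0,
    )


class TestUtiBranchProbs:
    def test_base_case_expansion(self):
        got = uti_branch_probs(0.6248, 0.34, 0.034)
        # independent product expansion
        p, r1, r2 = 0.6248, 0.34, 0.034
        expected = (1 - p, p * (1 - r1), p * r1 * (1 - r2), p * r1 * r2)
        assert got == pytest.approx(expected, abs=1e-15)
        assert got == pytest.approx((0.3752, 0.412368, 0.205209312, 0.007222688))

    def test_no_uti(self):
        assert uti_branch_probs(0.0, 0.34, 0.034) == (1.0, 0.0, 0.0, 0.0)

    def test_no_resistance(self):
        p = 0.5
        assert uti_branch_probs(p, 0.0, 0.3) == (0.5, 0.5, 0.0, 0.0)

    @given(p=probs01, r1=probs01, r2=probs01)
    def test_components_sum_to_one(self, p, r1, r2):
        assert sum(uti_branch_probs(p, r1, r2)) == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            uti_branch_probs(1.2, 0.3, 0.3)


class TestTreatmentEffect:
    def test_base_uti_adjustment(self):
        assert apply_treatment_effect(0.6248, 0.84) == pytest.approx(0.524832)

    def test_unity_rr_is_identity(self):
        assert apply_treatment_effect(0.37, 1.0) == 0.37

    def test_urosepsis_adjustment(self):
        assert apply_treatment_effect(0.0032, 0.90) == pytest.approx(0.00288)

    def test_capped_at_one(self):
        assert apply_treatment_effect(0.9, 1.5) == 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            apply_treatment_effect(-0.1, 0.9)


class TestAdjustedDeathProb:
    def test_zero_multiplier_returns_background(self):
        assert adjusted_death_prob(0.0123, 0.0) == 0.0123

    def test_closed_form(self):
        q, m = 0.0002, 145.27
        expected = 1 - math.exp(-(-math.log(1 - q)) * (1 + m))
        assert adjusted_death_prob(q, m) == pytest.approx(expected, abs=1e-12)

    def test_zero_background_stays_zero(self):
        assert adjusted_death_prob(0.0, 100.0) == 0.0

    def test_certain_death_stays_certain(self):
        assert adjusted_death_prob(1.0, 5.0) == 1.0

    @given(q=st.floats(min_value=0.0, max_value=0.999), m=st.floats(min_value=0.0, max_value=1000))
    def test_bounded_between_background_and_one(self, q, m):
        q2 = adjusted_death_prob(q, m)
        assert q - 1e-15 <= q2 <= 1.0

    def test_negative_multiplier_rejected(self):
        with pytest.raises(ValueError):
            adjusted_death_prob(0.1, -1.0)


class TestWeightedMultiplier:
    def test_base_case(self):
        assert round(weighted_uti_multiplier(145.27, 0.34), 2) == 49.39

    def test_zero_resistance(self):
        assert weighted_uti_multiplier(100.0, 0.0) == 0.0

    def test_direct_arithmetic(self):
        assert weighted_uti_multiplier(100.0, 0.5) == 50.0


class TestTransitionMatrix:
    @pytest.mark.parametrize("arm", ARMS)
    def test_rows_sum_to_one(self, params, arm):
        M = build_transition_matrix(params, arm, 0.001)
        assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(M >= 0)

    def test_dead_is_absorbing(self, params):
        M = build_transition_matrix(params, "pvc", 0.01)
        assert M[DEAD, DEAD] == 1.0
        assert np.all(M[DEAD, :DEAD] == 0.0)

    def test_no_renal_regression(self, params):
        M = build_transition_matrix(params, "pvc", 0.001)
        for r in RenalStage:
            for u in UtiLevel:
                s = state_index(r, u)
                for r2 in RenalStage:
                    if r2 < r:
                        for u2 in UtiLevel:
                            assert M[s, state_index(r2, u2)] == 0.0

    def test_all_zero_events_and_multipliers_keep_renal_stage(self, params):
        p = zeroed(params).with_overrides(
            m_uti_first_line=0.0, m_uti_resistant=0.0, m_uti_weighted=0.0,
            m_urosepsis=0.0, m_significant_impairment=0.0, m_renal_failure=0.0,
        )
        q = 0.02
        M = build_transition_matrix(p, "pvc", q)
        for r in RenalStage:
            s = state_index(r, UtiLevel.NO_UTI)
            assert M[s, s] == pytest.approx(1 - q)
            assert M[s, DEAD] == pytest.approx(q)

    def test_zero_progression_is_block_diagonal(self, params):
        p = params.with_overrides(p_progress_significant=0.0, p_progress_failure=0.0)
        M = build_transition_matrix(p, "pvc", 0.001)
        for r in RenalStage:
            for u in UtiLevel:
                s = state_index(r, u)
                for r2 in RenalStage:
                    if r2 != r:
                        for u2 in UtiLevel:
                            assert M[s, state_index(r2, u2)] == 0.0

    def test_elementwise_against_enumeration_oracle(self, params):
        """Brute-force enumeration of the branching tree, full parameters."""
        arm, q = "hydrophilic", 0.0008
        M = build_transition_matrix(params, arm, q)
        probs = arm_event_probs(params, arm)
        branch = uti_branch_probs(probs["uti"], params.r1, params.r2)
        m_sep = probs["urosepsis"] * params.m_urosepsis
        w = params.m_uti_weighted
        m_uti = [0.0, w, w, w]
        m_renal = [0.0, params.m_significant_impairment, params.m_renal_failure]
        prog = [params.p_progress_significant, params.p_progress_failure, 0.0]
        expected = np.zeros((N_STATES, N_STATES))
        for r in range(3):
            for u in range(4):
                s = r * 4 + u
                h = -math.log(1 - q)
                qd = 1 - math.exp(-h * (1 + m_renal[r] + m_uti[u] + m_sep))
                expected[s, 12] = qd
                moves = [(r, 1 - prog[r]), (r + 1, prog[r])] if r < 2 else [(r, 1.0)]
                for r2, pr in moves:
                    for u2 in range(4):
                        expected[s, r2 * 4 + u2] += (1 - qd) * pr * branch[u2]
        expected[12, 12] = 1.0
        assert np.allclose(M, expected, atol=1e-14)

    def test_state_specific_mode_splits_multipliers(self, params):
        p = params.with_overrides(uti_mortality_mode="state_specific")
        M = build_transition_matrix(p, "pvc", 0.001)
        # first-line UTI carries no excess beyond the urosepsis overlay
        s_first = state_index(RenalStage.NO_IMPAIRMENT, UtiLevel.FIRST_LINE)
        s_res = state_index(RenalStage.NO_IMPAIRMENT, UtiLevel.RESISTANT_FIRST)
        assert M[s_res, DEAD] > M[s_first, DEAD]

    def test_invalid_parameters_reported_by_field(self):
        with pytest.raises(ValueError, match="p_uti_pvc"):
            ModelParameters(p_uti_pvc=1.5)


@pytest.fixture(scope="module")
def trace(params, life_tables):
    return run_cohort(params, "pvc", life_tables["male"])


class TestRunCohort:
    def test_starts_healthy_and_uninfected(self, trace):
        assert trace.occupancy[0, state_index(0, 0)] == 1.0

    def test_occupancy_conserved_each_cycle(self, trace):
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)

    def test_dead_fraction_nondecreasing(self, trace):
        assert np.all(np.diff(trace.occupancy[:, DEAD]) >= -1e-12)

    def test_renal_progression_monotone(self, trace):
        # cumulative occupancy of significant+failure+dead never decreases
        idx = [state_index(r, u) for r in (1, 2) for u in range(4)] + [DEAD]
        mass = trace.occupancy[:, idx].sum(axis=1)
        assert np.all(np.diff(mass) >= -1e-12)

    def test_event_counts_bounded_by_alive_mass(self, trace):
        assert np.all(trace.events <= trace.alive[:, None] + 1e-12)

    def test_certain_death_at_entry(self, params):
        t = LifeTable(sex="male", age_start=36, q_annual=np.array([1.0]))
        tr = run_cohort(params, "pvc", t)
        assert tr.occupancy[-1, DEAD] == pytest.approx(1.0)
        assert tr.n_cycles <= 2

    def test_entry_age_outside_table_rejected(self, params):
        t = LifeTable(sex="male", age_start=50, q_annual=np.array([0.1, 1.0]))
        with pytest.raises(ValueError, match="entry age"):
            run_cohort(params, "pvc", t)

    def test_zeroed_disease_matches_survival_product_oracle(self, params, life_tables):
        table = life_tables["male"]
        tr = run_cohort(zeroed(params), "pvc", table)
        # independent survival product at monthly resolution
        surv, age0 = 1.0, params.entry_age
        for t in range(min(tr.n_cycles, 600)):
            assert tr.alive[t] == pytest.approx(surv, abs=1e-12)
            p = annual_to_monthly_prob(table.q_at(age0 + t // 12))
            surv *= 1 - p

    def test_hydrophilic_arm_has_fewer_utis(self, params, life_tables):
        tp = run_cohort(params, "pvc", life_tables["male"])
        th = run_cohort(params, "hydrophilic", life_tables["male"])
        assert th.events[:, 0].sum() < tp.events[:, 0].sum()

    def test_trace_frame_export(self, trace):
        df = trace.to_frame()
        assert len(df) == trace.n_cycles
        assert "dead" in df.columns
        assert {f"events_{e}" for e in EVENT_TYPES} <= set(df.columns)


class TestMicrosimOracle:
    def test_deterministic_background_only_agrees_exactly(self, params, schedules):
        # no disease, no background death until terminal: exact agreement
        q = np.zeros(6)
        q[-1] = 1.0
        table = LifeTable(sex="male", age_start=36, q_annual=q)
        p = zeroed(params)
        tr = run_cohort(p, "pvc", table)
        oc = accumulate(tr, *schedules, annual_rate=0.0)
        ms = microsim(p, "pvc", table, *schedules, annual_rate=0.0,
                      n_patients=100, seed=0)
        assert ms.lyg == pytest.approx(oc.lyg, abs=1e-9)
        assert ms.cost == pytest.approx(oc.cost, abs=1e-6)
        assert ms.qalys == pytest.approx(oc.qalys, abs=1e-9)
        assert ms.uti_count == 0.0 == oc.uti_count

    def test_same_seed_gives_identical_summary(self, params, life_tables, schedules):
        a = microsim(params, "pvc", life_tables["male"], *schedules, n_patients=500, seed=9)
        b = microsim(params, "pvc", life_tables["male"], *schedules, n_patients=500, seed=9)
        assert a == b

    def test_base_parameterization_within_monte_carlo_error(
        self, params, life_tables, schedules
    ):
        table = life_tables["male"]
        tr = run_cohort(params, "hydrophilic", table)
        oc = accumulate(tr, *schedules, annual_rate=0.05)
        ms = microsim(params, "hydrophilic", table, *schedules,
                      annual_rate=0.05, n_patients=6000, seed=21)
        for f in ("cost", "qalys", "lyg", "uti_count"):
            assert abs(ms.mean(f) - getattr(oc, f)) < 3 * ms.se(f), f
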