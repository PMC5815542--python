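"""Per-patient microsimulation used to validate the cohort engine.

The microsimulation applies exactly the per-state monthly transition
probabilities of the cohort model, but by sampling individual patients
instead of propagating a fraction vector, and accumulates the same
discounted outcomes per patient.  Its means converge to the cohort trace's
outcomes as the number of patients grows, providing an independent check of
the matrix propagation, event overlay and accumulation arithmetic.

One intentional difference: the per-cycle QALY floor at zero applies per
patient here but to the cohort aggregate in the deterministic engine.  Under
default parameters the floor never binds at the aggregate level and the
per-patient bias is far below Monte-Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .economics import CostSchedule, UtilitySchedule
from .lifetable import LifeTable, annual_to_monthly_prob
from .markov import (
    EVENT_TYPES,
    ModelParameters,
    RenalStage,
    UtiLevel,
    adjusted_death_prob,
    arm_event_probs,
    uti_branch_probs,
)

__all__ = ["MicrosimResult", "microsim"]

_OVERLAY = EVENT_TYPES[1:]


@dataclass(frozen=True)
class MicrosimResult:
    """Per-patient means and Monte-Carlo standard errors."""

    arm: str
    sex: str
    n_patients: int
    seed: int
    cost: float
    qalys: float
    lyg: float
    uti_count: float
    se_cost: float
    se_qalys: float
    se_lyg: float
    se_uti_count: float

    def mean(self, field: str) -> float:
        return getattr(self, field)

    def se(self, field: str) -> float:
        return getattr(self, f"se_{field}")


def microsim(
    params: ModelParameters,
    arm: str,
    life_table: LifeTable,
    cost_schedule: CostSchedule,
    utility_schedule: UtilitySchedule,
    annual_rate: float = 0.05,
    n_patients: int = 20_000,
    seed: int = 0,
) -> MicrosimResult:
    """Simulate ``n_patients`` individual trajectories and summarise outcomes.

    Start-of-cycle accounting, matching the cohort engine's default: a
    patient alive at the start of a cycle accrues that cycle's person-time,
    consumable and state costs, state utility, and sampled adverse events;
    death is resolved at the end of the cycle.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    params.validate()
    rng = np.random.default_rng(seed)
    entry_age = params.entry_age
    if entry_age < life_table.age_start or entry_age > life_table.terminal_age:
        raise ValueError("entry age outside life table range")

    probs = arm_event_probs(params, arm)
    branch = np.array(uti_branch_probs(probs["uti"], params.r1, params.r2))
    branch_cum = np.cumsum(branch)
    p_overlay = np.array([probs[ev] for ev in _OVERLAY])
    m_sepsis = probs["urosepsis"] * params.m_urosepsis

    if params.uti_mortality_mode == "weighted":
        w = params.m_uti_weighted
        m_uti = np.array([0.0, w, w, w])
    else:
        m_uti = np.array(
            [0.0, params.m_uti_first_line, params.m_uti_resistant, params.m_uti_resistant]
        )
    m_renal = np.array([0.0, params.m_significant_impairment, params.m_renal_failure])
    # death probability per (renal, uti) cell, recomputed per integer age
    mult = m_renal[:, None] + m_uti[None, :] + m_sepsis  # (3, 4)

    cath_cost = cost_schedule.catheter_monthly(arm)
    state_cost = np.array(
        [0.0, cost_schedule.significant_impairment_monthly, cost_schedule.renal_failure_monthly]
    )
    event_cost = np.array([cost_schedule.event_cost(ev) for ev in _OVERLAY])
    uti_cost = cost_schedule.event_cost("uti")
    u_state = np.array(
        [
            [utility_schedule.state_utility(r, u) for u in UtiLevel]
            for r in RenalStage
        ]
    )  # (3, 4) per-year utilities
    event_dec = np.array(
        [
            utility_schedule.bladder_stones,
            utility_schedule.kidney_stones,
            utility_schedule.urethral_injury,
            utility_schedule.urosepsis,
        ]
    )
    p_prog = np.array([params.p_progress_significant, params.p_progress_failure, 0.0])

    renal = np.zeros(n_patients, dtype=np.int8)
    uti = np.zeros(n_patients, dtype=np.int8)
    alive = np.ones(n_patients, dtype=bool)

    cost = np.zeros(n_patients)
    qalys = np.zeros(n_patients)
    lyg = np.zeros(n_patients)
    utis = np.zeros(n_patients)

    cycle = 0
    while alive.any():
        age = entry_age + cycle // 12
        if age > life_table.terminal_age:
            break
        q_m = annual_to_monthly_prob(life_table.q_at(age))
        q_death = np.array(
            [[adjusted_death_prob(q_m, m) for m in row] for row in mult]
        )  # (3, 4)
        df = (1.0 + annual_rate) ** (-cycle / 12.0)

        idx = np.flatnonzero(alive)
        r_a, u_a = renal[idx], uti[idx]

        lyg[idx] += df / 12.0
        cycle_cost = cath_cost + state_cost[r_a]
        cycle_q = u_state[r_a, u_a] / 12.0

        # sampled adverse events (UTI event count mirrors the cohort overlay)
        uti_ev = rng.random(idx.size) < probs["uti"]
        utis[idx] += uti_ev  # undiscounted
        cycle_cost = cycle_cost + uti_ev * uti_cost
        for j in range(len(_OVERLAY)):
            ev = rng.random(idx.size) < p_overlay[j]
            cycle_cost = cycle_cost + ev * event_cost[j]
            cycle_q = cycle_q - ev * event_dec[j] / 12.0

        cost[idx] += df * cycle_cost
        qalys[idx] += df * np.maximum(0.0, cycle_q)

        # end-of-cycle transition: death, renal progression, UTI redraw
        dies = rng.random(idx.size) < q_death[r_a, u_a]
        alive[idx[dies]] = False
        surv = idx[~dies]
        if surv.size:
            prog = rng.random(surv.size) < p_prog[renal[surv]]
            renal[surv[prog]] += 1
            draw = np.searchsorted(branch_cum, rng.random(surv.size), side="right")
            uti[surv] = np.minimum(draw, len(UtiLevel) - 1).astype(np.int8)
        cycle += 1

    def _mse(x):
        m = float(x.mean())
        se = float(x.std(ddof=1) / np.sqrt(n_patients)) if n_patients > 1 else 0.0
        return m, se

    c, se_c = _mse(cost)
    q, se_q = _mse(qalys)
    l, se_l = _mse(lyg)
    u, se_u = _mse(utis)
    return MicrosimResult(
        arm=arm,
        sex=life_table.sex,
        n_patients=n_patients,
        seed=seed,
        cost=c,
        qalys=q,
        lyg=l,
        uti_count=u,
        se_cost=se_c,
        se_qalys=se_q,
        se_lyg=se_l,
        se_uti_count=se_u,
    )
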