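"""Costs, utilities and discounted outcome accumulation over a cohort trace.

All monetary amounts are BRL.  Costs, QALYs and LYG are discounted at an
annual rate (default 5%) applied per monthly cycle as ``(1+r)^(-t/12)``;
UTI counts are never discounted.

QALY accounting: renal-stage and current-cycle UTI decrements apply through
state occupancy; stones, urethral injury and urosepsis decrements apply per
expected overlay event.  Each event decrement lasts one cycle (1/12 year),
matching the one-cycle episode structure of the state model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .markov import (
    DEAD,
    EVENT_TYPES,
    N_STATES,
    RenalStage,
    UtiLevel,
    CohortTrace,
    state_index,
)

__all__ = [
    "CostSchedule",
    "UtilitySchedule",
    "ArmOutcomes",
    "discount_factor",
    "cycle_cost",
    "cycle_qaly",
    "accumulate",
    "combine_outcomes",
]

_EV = {ev: i for i, ev in enumerate(EVENT_TYPES)}


@dataclass(frozen=True)
class CostSchedule:
    """BRL cost inputs: monthly consumables per arm, per-event treatment
    costs, and per-state monthly costs of impaired renal function.

    Lubricant applies to the PVC arm only and scales linearly with
    ``tubes_per_day`` from the 2-tubes/day base price (half a tube per
    catheterization, four catheterizations a day).
    """

    catheter_monthly_pvc: float = 74.27
    catheter_monthly_hydrophilic: float = 608.27
    lubricant_monthly_base: float = 132.75  # at 2 tubes/day
    tubes_per_day: float = 2.0
    uti_event: float = 554.16
    uti_antibiotics: float = 60.50  # once per UTI event, any line
    urosepsis_event: float = 708.36
    urethral_injury_event: float = 605.33
    kidney_stones_event: float = 524.30
    bladder_stones_event: float = 721.95
    significant_impairment_monthly: float = 82.60
    renal_failure_monthly: float = 2589.02

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")

    @property
    def lubricant_monthly(self) -> float:
        return self.lubricant_monthly_base * self.tubes_per_day / 2.0

    def catheter_monthly(self, arm: str) -> float:
        if arm == "pvc":
            return self.catheter_monthly_pvc + self.lubricant_monthly
        if arm == "hydrophilic":
            return self.catheter_monthly_hydrophilic
        raise ValueError(f"unknown arm {arm!r}")

    def event_cost(self, event: str) -> float:
        if event == "uti":
            return self.uti_event + self.uti_antibiotics
        return getattr(self, f"{event}_event")

    def with_overrides(self, **kwargs) -> "CostSchedule":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class UtilitySchedule:
    """Baseline utility and decrements.

    ``baseline`` is the utility of an uncomplicated catheter user; it is an
    assumption of this package (no published value exists for the cohort),
    exposed in configuration.  State decrements (renal stage, current UTI
    level) enter through occupancy; event decrements through overlay counts.
    """

    baseline: float = 0.50  # assumption, not a published input
    uti: float = 0.060
    uti_resistant: float = 0.104
    kidney_stones: float = 0.050
    bladder_stones: float = 0.050
    urethral_injury: float = 0.104
    urosepsis: float = 0.160
    significant_impairment: float = 0.155
    renal_failure: float = 0.250

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline <= 1.0:
            raise ValueError("baseline utility must lie in [0, 1]")
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")

    def state_utility(self, renal: RenalStage, uti: UtiLevel) -> float:
        """Per-year utility of an alive state, floored at 0."""
        dec = 0.0
        if renal == RenalStage.SIGNIFICANT_IMPAIRMENT:
            dec += self.significant_impairment
        elif renal == RenalStage.RENAL_FAILURE:
            dec += self.renal_failure
        if uti == UtiLevel.FIRST_LINE:
            dec += self.uti
        elif uti in (UtiLevel.RESISTANT_FIRST, UtiLevel.RESISTANT_SECOND):
            dec += self.uti_resistant
        return max(0.0, self.baseline - dec)

    def with_overrides(self, **kwargs) -> "UtilitySchedule":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ArmOutcomes:
    """Discounted lifetime cost, QALYs and LYG plus undiscounted UTI count
    for one strategy."""

    arm: str
    cost: float
    qalys: float
    lyg: float
    uti_count: float
    components: dict = field(default_factory=dict)


def discount_factor(annual_rate: float, cycle_index: int) -> float:
    """Discount factor for a monthly cycle: (1+r)^(-t/12)."""
    if annual_rate < 0:
        raise ValueError("discount rate must be nonnegative")
    if cycle_index < 0:
        raise ValueError("cycle index must be nonnegative")
    return (1.0 + annual_rate) ** (-cycle_index / 12.0)


def _state_utility_vector(us: UtilitySchedule) -> np.ndarray:
    u = np.zeros(N_STATES)
    for r in RenalStage:
        for lvl in UtiLevel:
            u[state_index(r, lvl)] = us.state_utility(r, lvl)
    return u


def _state_cost_vector(cs: CostSchedule, arm: str) -> np.ndarray:
    c = np.zeros(N_STATES)
    cath = cs.catheter_monthly(arm)
    for r in RenalStage:
        extra = 0.0
        if r == RenalStage.SIGNIFICANT_IMPAIRMENT:
            extra = cs.significant_impairment_monthly
        elif r == RenalStage.RENAL_FAILURE:
            extra = cs.renal_failure_monthly
        for lvl in UtiLevel:
            c[state_index(r, lvl)] = cath + extra
    return c


def cycle_cost(
    trace_row: np.ndarray, overlay_row: np.ndarray, schedule: CostSchedule, arm: str
) -> float:
    """Undiscounted BRL cost of one cycle: consumables and renal-state costs
    on occupancy, treatment costs on expected event counts."""
    state_costs = _state_cost_vector(schedule, arm)
    total = float(trace_row @ state_costs)
    for ev, j in _EV.items():
        total += overlay_row[j] * schedule.event_cost(ev)
    return total


def cycle_qaly(
    trace_row: np.ndarray, overlay_row: np.ndarray, utilities: UtilitySchedule
) -> float:
    """Undiscounted QALYs accrued in one cycle (1/12 year per alive member),
    never negative."""
    u = _state_utility_vector(utilities)
    q = float(trace_row @ u) / 12.0
    for ev in ("kidney_stones", "bladder_stones", "urethral_injury", "urosepsis"):
        q -= overlay_row[_EV[ev]] * getattr(utilities, ev) / 12.0
    return max(0.0, q)


def accumulate(
    trace: CohortTrace,
    cost_schedule: CostSchedule,
    utility_schedule: UtilitySchedule,
    annual_rate: float = 0.05,
    half_cycle: bool = False,
) -> ArmOutcomes:
    """Discounted totals over a cohort trace.

    With ``half_cycle`` the occupancy (and the occupancy-proportional event
    counts) are trapezoid-averaged between successive cycles — members are
    credited half a cycle in the cycle they die — which reproduces the
    mid-period life-table convention.  Default is plain start-of-cycle
    accounting.
    """
    if annual_rate < 0:
        raise ValueError("discount rate must be nonnegative")
    occ = trace.occupancy
    ev = trace.events
    if half_cycle:
        # trapezoid with an all-dead virtual row after the final cycle
        occ_next = np.vstack([occ[1:], occ[-1:]])
        occ_next[-1, :] = 0.0
        occ_next[-1, DEAD] = 1.0
        ev_next = np.vstack([ev[1:], np.zeros((1, ev.shape[1]))])
        occ = (occ + occ_next) / 2.0
        # renormalise the virtual tail row's dead mass
        occ[:, DEAD] = 1.0 - occ[:, : DEAD].sum(axis=1)
        ev = (ev + ev_next) / 2.0

    t = np.arange(occ.shape[0])
    df = (1.0 + annual_rate) ** (-t / 12.0)
    alive = 1.0 - occ[:, DEAD]

    state_costs = _state_cost_vector(cost_schedule, trace.arm)
    event_costs = np.array([cost_schedule.event_cost(e) for e in EVENT_TYPES])
    u_vec = _state_utility_vector(utility_schedule)
    ev_dec = np.array(
        [
            0.0,  # UTI decrement enters through state occupancy
            utility_schedule.bladder_stones,
            utility_schedule.kidney_stones,
            utility_schedule.urethral_injury,
            utility_schedule.urosepsis,
        ]
    )

    cost_state_cycle = occ @ state_costs
    cost_event_cycle = ev @ event_costs
    qaly_cycle = np.maximum(0.0, (occ @ u_vec) / 12.0 - (ev @ ev_dec) / 12.0)

    components = {
        "state_cost": float(cost_state_cycle @ df),
        "event_cost": float(cost_event_cycle @ df),
        "lubricant_cost": float((alive * cost_schedule.lubricant_monthly) @ df)
        if trace.arm == "pvc"
        else 0.0,
    }

    return ArmOutcomes(
        arm=trace.arm,
        cost=float((cost_state_cycle + cost_event_cycle) @ df),
        qalys=float(qaly_cycle @ df),
        lyg=float((alive / 12.0) @ df),
        uti_count=float(ev[:, _EV["uti"]].sum()),
        components=components,
    )


def combine_outcomes(outcomes: list[ArmOutcomes], weights: list[float]) -> ArmOutcomes:
    """Weight-average outcomes across cohorts (e.g. 0.8 male / 0.2 female)."""
    if len(outcomes) != len(weights) or not outcomes:
        raise ValueError("outcomes and weights must be non-empty and aligned")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    arms = {o.arm for o in outcomes}
    if len(arms) != 1:
        raise ValueError("cannot combine outcomes from different arms")
    comp_keys = outcomes[0].components.keys()
    return ArmOutcomes(
        arm=outcomes[0].arm,
        cost=sum(w * o.cost for o, w in zip(outcomes, weights)),
        qalys=sum(w * o.qalys for o, w in zip(outcomes, weights)),
        lyg=sum(w * o.lyg for o, w in zip(outcomes, weights)),
        uti_count=sum(w * o.uti_count for o, w in zip(outcomes, weights)),
        components={
            k: sum(w * o.components.get(k, 0.0) for o, w in zip(outcomes, weights))
            for k in comp_keys
        },
    )
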