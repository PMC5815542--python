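"""Markov cohort engine: 3 renal stages × 4 UTI levels plus death.

State space
-----------
Alive states are the product of a renal dimension (no impairment →
significant impairment → renal failure, progression only) and a UTI
dimension (no UTI / UTI on first-line antibiotics / resistant to first
line / resistant to second line).  Death is the single absorbing state.
A cycle is one month.  Every new catheter user enters in (no impairment,
no UTI).

Each cycle, survivors are redrawn across the four UTI levels from the
resistance cascade — a UTI episode lasts exactly one cycle — and may
progress one renal stage; it is not possible to regress.  Regardless of
renal stage, the cohort remains subject to the same UTI risk.

Mortality is the life-table background hazard scaled by excess-hazard
multipliers: ``q' = 1 - exp(-h (1 + m))`` with ``h = -ln(1-q)``, where
``m`` adds the renal-stage multiplier, the UTI multiplier of the current
level, and the urosepsis multiplier weighted by the per-cycle urosepsis
probability.  A multiplier of 0 reproduces background mortality exactly.

Adverse events other than UTI (bladder stones, kidney stones, urethral
injury, urosepsis) are expected-count overlays on alive occupancy, not
Markov states; they carry costs, utility decrements and — for urosepsis —
the mortality load described above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np
import pandas as pd

from .lifetable import LifeTable, annual_to_monthly_prob

__all__ = [
    "RenalStage",
    "UtiLevel",
    "ModelParameters",
    "CohortTrace",
    "ARMS",
    "EVENT_TYPES",
    "N_STATES",
    "DEAD",
    "state_index",
    "state_names",
    "uti_branch_probs",
    "apply_treatment_effect",
    "adjusted_death_prob",
    "weighted_uti_multiplier",
    "arm_event_probs",
    "build_transition_matrix",
    "run_cohort",
]

ARMS = ("pvc", "hydrophilic")

#: Per-cycle expected-count overlays tracked alongside state occupancy.
EVENT_TYPES = ("uti", "bladder_stones", "kidney_stones", "urethral_injury", "urosepsis")
OVERLAY_EVENTS = EVENT_TYPES[1:]


class RenalStage(IntEnum):
    NO_IMPAIRMENT = 0
    SIGNIFICANT_IMPAIRMENT = 1
    RENAL_FAILURE = 2


class UtiLevel(IntEnum):
    NO_UTI = 0
    FIRST_LINE = 1
    RESISTANT_FIRST = 2
    RESISTANT_SECOND = 3


N_ALIVE = len(RenalStage) * len(UtiLevel)  # 12
DEAD = N_ALIVE
N_STATES = N_ALIVE + 1  # 13


def state_index(renal: RenalStage | int, uti: UtiLevel | int) -> int:
    return int(renal) * len(UtiLevel) + int(uti)


def state_names() -> list[str]:
    names = [
        f"{r.name.lower()}|{u.name.lower()}" for r in RenalStage for u in UtiLevel
    ]
    names.append("dead")
    return names


@dataclass(frozen=True)
class ModelParameters:
    """Every rate, treatment effect, resistance probability and mortality
    multiplier driving transitions.  Probabilities are monthly; multipliers
    are excess relative hazards (0 = background mortality)."""

    p_uti_pvc: float = 0.6248
    rr_uti: float = 0.84
    r1: float = 0.34  # first-line (ciprofloxacin) resistance
    r2: float = 0.034  # second-line (cefuroxime) resistance
    overlay_event_probs: dict = field(
        default_factory=lambda: {
            "bladder_stones": 0.0012,
            "kidney_stones": 0.0012,
            "urethral_injury": 0.0019,
            "urosepsis": 0.0032,
        }
    )
    rr_other: float = 0.90  # hydrophilic effect on all overlay events
    p_progress_significant: float = 0.0004  # no impairment → significant, assumption
    p_progress_failure: float = 0.0029  # significant → failure, assumption
    m_uti_first_line: float = 0.0
    m_uti_resistant: float = 145.27
    #: resistance-weighted multiplier applied to all active-UTI states in
    #: weighted mode; an explicit model input (= 145.27 × 0.34 at base case),
    #: deliberately NOT recomputed when r1 is varied in sensitivity analyses.
    m_uti_weighted: float = 49.3918
    m_urosepsis: float = 797.6
    m_significant_impairment: float = 18.0
    m_renal_failure: float = 54.0
    uti_mortality_mode: str = "weighted"  # or "state_specific"
    rate_to_prob: bool = False
    entry_age: int = 36
    proportion_male: float = 0.80

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        bad = []
        probs = {
            "p_uti_pvc": self.p_uti_pvc,
            "r1": self.r1,
            "r2": self.r2,
            "p_progress_significant": self.p_progress_significant,
            "p_progress_failure": self.p_progress_failure,
            "proportion_male": self.proportion_male,
            **{f"overlay_event_probs.{k}": v for k, v in self.overlay_event_probs.items()},
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                bad.append(f"{name}={v} outside [0, 1]")
        for name, v in {
            "rr_uti": self.rr_uti,
            "rr_other": self.rr_other,
            "m_uti_first_line": self.m_uti_first_line,
            "m_uti_resistant": self.m_uti_resistant,
            "m_uti_weighted": self.m_uti_weighted,
            "m_urosepsis": self.m_urosepsis,
            "m_significant_impairment": self.m_significant_impairment,
            "m_renal_failure": self.m_renal_failure,
        }.items():
            if v < 0:
                bad.append(f"{name}={v} must be nonnegative")
        if set(self.overlay_event_probs) != set(OVERLAY_EVENTS):
            bad.append(f"overlay_event_probs keys must be {OVERLAY_EVENTS}")
        if self.uti_mortality_mode not in ("weighted", "state_specific"):
            bad.append(f"uti_mortality_mode={self.uti_mortality_mode!r} unknown")
        if bad:
            raise ValueError("invalid parameters: " + "; ".join(bad))

    def with_overrides(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)


def uti_branch_probs(p_uti: float, r1: float, r2: float):
    """Split a monthly UTI probability across the resistance cascade.

    Returns (no UTI, first-line, resistant-to-first, resistant-to-second) =
    (1-p, p(1-r1), p·r1(1-r2), p·r1·r2); the four components sum to 1.
    """
    for name, v in (("p_uti", p_uti), ("r1", r1), ("r2", r2)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return (
        1.0 - p_uti,
        p_uti * (1.0 - r1),
        p_uti * r1 * (1.0 - r2),
        p_uti * r1 * r2,
    )


def apply_treatment_effect(p_baseline: float, rr: float) -> float:
    """Scale a baseline probability by a relative risk, capped at 1."""
    if p_baseline < 0 or rr < 0:
        raise ValueError("probability and relative risk must be nonnegative")
    return min(p_baseline * rr, 1.0)


def adjusted_death_prob(q_monthly: float, multiplier: float) -> float:
    """Scale background monthly mortality by an excess-hazard multiplier.

    h = -ln(1-q); q' = 1 - exp(-h (1+m)).  m = 0 returns q exactly; q = 1
    stays 1 for any m.
    """
    if not 0.0 <= q_monthly <= 1.0:
        raise ValueError(f"q_monthly={q_monthly} outside [0, 1]")
    if multiplier < 0:
        raise ValueError("mortality multiplier must be nonnegative")
    if q_monthly == 1.0:
        return 1.0
    if multiplier == 0.0:
        return q_monthly
    h = -math.log1p(-q_monthly)
    return 1.0 - math.exp(-h * (1.0 + multiplier))


def weighted_uti_multiplier(m_resistant: float, r1: float) -> float:
    """Resistance-weighted UTI mortality multiplier: m_resistant × r1
    (first-line UTIs carry multiplier 0, resistant ones m_resistant)."""
    if m_resistant < 0:
        raise ValueError("multiplier must be nonnegative")
    if not 0.0 <= r1 <= 1.0:
        raise ValueError("r1 must lie in [0, 1]")
    return m_resistant * r1


def arm_event_probs(params: ModelParameters, arm: str) -> dict:
    """Monthly event probabilities for one arm, treatment effect applied.

    Returns a dict over :data:`EVENT_TYPES`.  With ``rate_to_prob`` the
    UTI figure is treated as an event rate and converted via 1-exp(-rate).
    """
    if arm not in ARMS:
        raise ValueError(f"arm must be one of {ARMS}, got {arm!r}")
    rr_u = params.rr_uti if arm == "hydrophilic" else 1.0
    rr_o = params.rr_other if arm == "hydrophilic" else 1.0
    if params.rate_to_prob:
        p_uti = 1.0 - math.exp(-params.p_uti_pvc * rr_u)
    else:
        p_uti = apply_treatment_effect(params.p_uti_pvc, rr_u)
    probs = {"uti": p_uti}
    for ev, p in params.overlay_event_probs.items():
        probs[ev] = apply_treatment_effect(p, rr_o)
    return probs


def _uti_multipliers(params: ModelParameters) -> np.ndarray:
    """Multiplier per UTI level under the configured mode."""
    if params.uti_mortality_mode == "weighted":
        w = params.m_uti_weighted
        return np.array([0.0, w, w, w])
    return np.array(
        [0.0, params.m_uti_first_line, params.m_uti_resistant, params.m_uti_resistant]
    )


def build_transition_matrix(
    params: ModelParameters, arm: str, q_monthly_background: float
) -> np.ndarray:
    """Row-stochastic 13×13 monthly transition matrix for one arm and one
    background mortality level.

    Renal and UTI excess hazards add (h × (1 + m_renal + m_uti + p_sep·m_sep));
    survivors progress at most one renal stage and redraw the UTI level from
    the resistance cascade.
    """
    params.validate()
    if not 0.0 <= q_monthly_background <= 1.0:
        raise ValueError("q_monthly_background must lie in [0, 1]")
    probs = arm_event_probs(params, arm)
    branch = np.array(uti_branch_probs(probs["uti"], params.r1, params.r2))
    m_uti = _uti_multipliers(params)
    m_renal = np.array(
        [0.0, params.m_significant_impairment, params.m_renal_failure]
    )
    m_sepsis = probs["urosepsis"] * params.m_urosepsis

    M = np.zeros((N_STATES, N_STATES))
    renal_moves = {
        RenalStage.NO_IMPAIRMENT: (
            (RenalStage.NO_IMPAIRMENT, 1.0 - params.p_progress_significant),
            (RenalStage.SIGNIFICANT_IMPAIRMENT, params.p_progress_significant),
        ),
        RenalStage.SIGNIFICANT_IMPAIRMENT: (
            (RenalStage.SIGNIFICANT_IMPAIRMENT, 1.0 - params.p_progress_failure),
            (RenalStage.RENAL_FAILURE, params.p_progress_failure),
        ),
        RenalStage.RENAL_FAILURE: ((RenalStage.RENAL_FAILURE, 1.0),),
    }
    for r in RenalStage:
        for u in UtiLevel:
            s = state_index(r, u)
            q_d = adjusted_death_prob(
                q_monthly_background, m_renal[r] + m_uti[u] + m_sepsis
            )
            M[s, DEAD] = q_d
            surv = 1.0 - q_d
            for r_next, p_r in renal_moves[r]:
                if p_r == 0.0:
                    continue
                for u_next in UtiLevel:
                    M[s, state_index(r_next, u_next)] += surv * p_r * branch[u_next]
    M[DEAD, DEAD] = 1.0
    return M


@dataclass(frozen=True)
class CohortTrace:
    """Cycle-by-cycle cohort occupancy plus expected overlay-event counts.

    ``occupancy[t]`` is the state distribution at the start of cycle ``t``;
    ``events[t]`` the expected per-member event counts accrued during that
    cycle (computed on start-of-cycle alive mass).
    """

    occupancy: np.ndarray = field(repr=False)  # (cycles, 13)
    events: np.ndarray = field(repr=False)  # (cycles, 5) in EVENT_TYPES order
    arm: str
    sex: str
    entry_age: int

    def __post_init__(self) -> None:
        occ, ev = self.occupancy, self.events
        if occ.ndim != 2 or occ.shape[1] != N_STATES:
            raise ValueError("occupancy must have 13 state columns")
        if ev.shape != (occ.shape[0], len(EVENT_TYPES)):
            raise ValueError("events must align with occupancy rows")
        if np.any(occ < -1e-12) or np.any(ev < -1e-12):
            raise ValueError("occupancy and event counts must be nonnegative")
        sums = occ.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("each cycle's occupancy must sum to 1")
        if np.any(np.diff(occ[:, DEAD]) < -1e-12):
            raise ValueError("dead occupancy must be nondecreasing")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0]

    @property
    def alive(self) -> np.ndarray:
        """Alive fraction at the start of each cycle."""
        return 1.0 - self.occupancy[:, DEAD]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=state_names())
        for j, ev in enumerate(EVENT_TYPES):
            df[f"events_{ev}"] = self.events[:, j]
        df.insert(0, "cycle", np.arange(self.n_cycles))
        return df


def run_cohort(
    params: ModelParameters,
    arm: str,
    life_table: LifeTable,
    max_age: int | None = None,
    extinction: float = 1e-9,
) -> CohortTrace:
    """Propagate a cohort entering at ``params.entry_age`` in (no impairment,
    no UTI) through monthly cycles until extinction or ``max_age``.

    The transition matrix is rebuilt whenever the cohort's integer age (and
    hence the background annual q) changes.
    """
    entry_age = params.entry_age
    if entry_age < life_table.age_start or entry_age > life_table.terminal_age:
        raise ValueError(
            f"entry age {entry_age} outside life table range "
            f"[{life_table.age_start}, {life_table.terminal_age}]"
        )
    if max_age is None:
        max_age = life_table.terminal_age
    if max_age > life_table.terminal_age:
        raise ValueError("max_age exceeds life-table terminal age")

    probs = arm_event_probs(params, arm)
    p_events = np.array([probs[ev] for ev in EVENT_TYPES])

    matrices: dict[int, np.ndarray] = {}
    state = np.zeros(N_STATES)
    state[state_index(RenalStage.NO_IMPAIRMENT, UtiLevel.NO_UTI)] = 1.0

    occ_rows = [state.copy()]
    ev_rows = [(1.0 - state[DEAD]) * p_events]
    cycle = 0
    while True:
        age = entry_age + cycle // 12
        alive = 1.0 - state[DEAD]
        if alive < extinction or age > max_age:
            break
        M = matrices.get(age)
        if M is None:
            q_m = annual_to_monthly_prob(life_table.q_at(age))
            M = build_transition_matrix(params, arm, q_m)
            matrices[age] = M
        state = state @ M
        cycle += 1
        occ_rows.append(state.copy())
        ev_rows.append((1.0 - state[DEAD]) * p_events)

    return CohortTrace(
        occupancy=np.array(occ_rows),
        events=np.array(ev_rows),
        arm=arm,
        sex=life_table.sex,
        entry_age=entry_age,
    )
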