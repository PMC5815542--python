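"""Run configuration: a single validated object covering cohort definition,
event rates, treatment effects, costs, utilities, discounting and life-table
provenance, loadable from YAML.

Unknown keys are rejected and out-of-range values produce errors naming the
offending field path.  Defaults marked ``assumption`` in the packaged config
are package choices, not published inputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
from importlib import resources
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .economics import CostSchedule, UtilitySchedule
from .lifetable import (
    DEFAULT_AGE_END,
    DEFAULT_GM_PARAMS,
    LifeTable,
    gompertz_makeham_life_table,
    read_life_table,
)
from .markov import ModelParameters

__all__ = [
    "RunConfig",
    "load_config",
    "write_config",
    "default_config",
    "secondary_preset",
    "config_hash",
    "apply_override",
]


class _Strict(BaseModel):
    model_config = {"extra": "forbid", "frozen": False}


class CohortConfig(_Strict):
    entry_age: int = Field(36, ge=0)
    proportion_male: float = Field(0.80, ge=0.0, le=1.0)


class EventRates(_Strict):
    """Monthly adverse-event probabilities for the uncoated-PVC baseline."""

    uti: float = Field(0.6248, ge=0.0, le=1.0)
    bladder_stones: float = Field(0.0012, ge=0.0, le=1.0)
    kidney_stones: float = Field(0.0012, ge=0.0, le=1.0)
    urethral_injury: float = Field(0.0019, ge=0.0, le=1.0)
    urosepsis: float = Field(0.0032, ge=0.0, le=1.0)


class TreatmentEffect(_Strict):
    """Relative risks, hydrophilic-coated vs PVC."""

    uti: float = Field(0.84, ge=0.0)
    other_events: float = Field(0.90, ge=0.0)


class Resistance(_Strict):
    first_line: float = Field(0.34, ge=0.0, le=1.0)  # ciprofloxacin
    second_line: float = Field(0.034, ge=0.0, le=1.0)  # cefuroxime


class RenalProgression(_Strict):
    """Monthly progression probabilities; assumptions, not published inputs."""

    no_to_significant: float = Field(0.0004, ge=0.0, le=1.0)
    significant_to_failure: float = Field(0.0029, ge=0.0, le=1.0)


class MortalityMultipliers(_Strict):
    """Excess-hazard multipliers over background mortality (0 = none)."""

    uti_first_line: float = Field(0.0, ge=0.0)
    uti_resistant: float = Field(145.27, ge=0.0)
    # resistance-weighted input (145.27 × 0.34); a fixed model input, not
    # recomputed when the resistance rate is varied one-way
    uti_weighted: float = Field(49.3918, ge=0.0)
    urosepsis: float = Field(797.6, ge=0.0)
    significant_impairment: float = Field(18.0, ge=0.0)
    renal_failure: float = Field(54.0, ge=0.0)


class Flags(_Strict):
    uti_mortality_mode: Literal["weighted", "state_specific"] = "weighted"
    rate_to_prob: bool = False
    half_cycle: bool = False


class CostsConfig(_Strict):
    catheter_pvc_monthly: float = Field(74.27, ge=0.0)
    catheter_hydrophilic_monthly: float = Field(608.27, ge=0.0)
    lubricant_monthly: float = Field(132.75, ge=0.0)  # at 2 tubes/day
    tubes_per_day: float = Field(2.0, gt=0.0)
    uti_event: float = Field(554.16, ge=0.0)
    uti_antibiotics: float = Field(60.50, ge=0.0)
    urosepsis_event: float = Field(708.36, ge=0.0)
    urethral_injury_event: float = Field(605.33, ge=0.0)
    kidney_stones_event: float = Field(524.30, ge=0.0)
    bladder_stones_event: float = Field(721.95, ge=0.0)
    significant_impairment_monthly: float = Field(82.60, ge=0.0)
    renal_failure_monthly: float = Field(2589.02, ge=0.0)


class UtilitiesConfig(_Strict):
    baseline: float = Field(0.50, ge=0.0, le=1.0)  # assumption
    uti: float = Field(0.060, ge=0.0)
    uti_resistant: float = Field(0.104, ge=0.0)
    kidney_stones: float = Field(0.050, ge=0.0)
    bladder_stones: float = Field(0.050, ge=0.0)
    urethral_injury: float = Field(0.104, ge=0.0)
    urosepsis: float = Field(0.160, ge=0.0)
    significant_impairment: float = Field(0.155, ge=0.0)
    renal_failure: float = Field(0.250, ge=0.0)


class EconomicsConfig(_Strict):
    discount_rate_annual: float = Field(0.05, ge=0.0)
    threshold_per_qaly: float = Field(147_000.0, ge=0.0)


class GMParams(_Strict):
    a: float = Field(..., ge=0.0)
    b: float = Field(..., ge=0.0)
    c: float = Field(..., ge=1.0)


class LifeTableConfig(_Strict):
    """Either synthetic Gompertz–Makeham parameters per sex, or file paths."""

    kind: Literal["synthetic", "file"] = "synthetic"
    age_start: int = Field(0, ge=0)
    age_end: int = Field(DEFAULT_AGE_END, gt=0)
    male: GMParams = GMParams(**DEFAULT_GM_PARAMS["male"])
    female: GMParams = GMParams(**DEFAULT_GM_PARAMS["female"])
    male_path: Optional[str] = None
    female_path: Optional[str] = None

    @model_validator(mode="after")
    def _check_paths(self):
        if self.kind == "file" and (self.male_path is None or self.female_path is None):
            raise ValueError("life_table.kind='file' requires male_path and female_path")
        return self


class RunConfig(_Strict):
    analysis: Literal["primary", "secondary"] = "primary"
    seed: int = Field(0, ge=0)
    cohort: CohortConfig = CohortConfig()
    event_rates: EventRates = EventRates()
    treatment_effect: TreatmentEffect = TreatmentEffect()
    resistance: Resistance = Resistance()
    renal_progression: RenalProgression = RenalProgression()
    mortality_multipliers: MortalityMultipliers = MortalityMultipliers()
    flags: Flags = Flags()
    costs: CostsConfig = CostsConfig()
    utilities: UtilitiesConfig = UtilitiesConfig()
    economics: EconomicsConfig = EconomicsConfig()
    life_table: LifeTableConfig = LifeTableConfig()

    # -- builders -----------------------------------------------------------
    def model_parameters(self) -> ModelParameters:
        return ModelParameters(
            p_uti_pvc=self.event_rates.uti,
            rr_uti=self.treatment_effect.uti,
            r1=self.resistance.first_line,
            r2=self.resistance.second_line,
            overlay_event_probs={
                "bladder_stones": self.event_rates.bladder_stones,
                "kidney_stones": self.event_rates.kidney_stones,
                "urethral_injury": self.event_rates.urethral_injury,
                "urosepsis": self.event_rates.urosepsis,
            },
            rr_other=self.treatment_effect.other_events,
            p_progress_significant=self.renal_progression.no_to_significant,
            p_progress_failure=self.renal_progression.significant_to_failure,
            m_uti_first_line=self.mortality_multipliers.uti_first_line,
            m_uti_resistant=self.mortality_multipliers.uti_resistant,
            m_uti_weighted=self.mortality_multipliers.uti_weighted,
            m_urosepsis=self.mortality_multipliers.urosepsis,
            m_significant_impairment=self.mortality_multipliers.significant_impairment,
            m_renal_failure=self.mortality_multipliers.renal_failure,
            uti_mortality_mode=self.flags.uti_mortality_mode,
            rate_to_prob=self.flags.rate_to_prob,
            entry_age=self.cohort.entry_age,
            proportion_male=self.cohort.proportion_male,
        )

    def cost_schedule(self) -> CostSchedule:
        c = self.costs
        return CostSchedule(
            catheter_monthly_pvc=c.catheter_pvc_monthly,
            catheter_monthly_hydrophilic=c.catheter_hydrophilic_monthly,
            lubricant_monthly_base=c.lubricant_monthly,
            tubes_per_day=c.tubes_per_day,
            uti_event=c.uti_event,
            uti_antibiotics=c.uti_antibiotics,
            urosepsis_event=c.urosepsis_event,
            urethral_injury_event=c.urethral_injury_event,
            kidney_stones_event=c.kidney_stones_event,
            bladder_stones_event=c.bladder_stones_event,
            significant_impairment_monthly=c.significant_impairment_monthly,
            renal_failure_monthly=c.renal_failure_monthly,
        )

    def utility_schedule(self) -> UtilitySchedule:
        u = self.utilities
        return UtilitySchedule(
            baseline=u.baseline,
            uti=u.uti,
            uti_resistant=u.uti_resistant,
            kidney_stones=u.kidney_stones,
            bladder_stones=u.bladder_stones,
            urethral_injury=u.urethral_injury,
            urosepsis=u.urosepsis,
            significant_impairment=u.significant_impairment,
            renal_failure=u.renal_failure,
        )

    def build_life_tables(self) -> dict[str, LifeTable]:
        lt = self.life_table
        if lt.kind == "file":
            return {
                "male": read_life_table(lt.male_path),
                "female": read_life_table(lt.female_path),
            }
        return {
            sex: gompertz_makeham_life_table(
                a=getattr(lt, sex).a,
                b=getattr(lt, sex).b,
                c=getattr(lt, sex).c,
                age_start=lt.age_start,
                age_end=lt.age_end,
                sex=sex,
            )
            for sex in ("male", "female")
        }


def secondary_preset(config: RunConfig) -> RunConfig:
    """The UTI-only scenario: zero the stone, urethral-injury and urosepsis
    probabilities so UTIs are the sole adverse event."""
    cfg = config.model_copy(deep=True)
    cfg.analysis = "secondary"
    cfg.event_rates.bladder_stones = 0.0
    cfg.event_rates.kidney_stones = 0.0
    cfg.event_rates.urethral_injury = 0.0
    cfg.event_rates.urosepsis = 0.0
    return cfg


def load_config(path) -> RunConfig:
    """Load and fully validate a YAML run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as err:
        msgs = [
            ".".join(str(p) for p in e["loc"]) + ": " + e["msg"] for e in err.errors()
        ]
        raise ValueError("invalid configuration: " + "; ".join(msgs)) from err


def write_config(config: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=True)


def default_config() -> RunConfig:
    """The packaged base case (primary analysis)."""
    with resources.as_file(
        resources.files("cathcea").joinpath("data/base_case.yaml")
    ) as p:
        return load_config(p)


def config_hash(config: RunConfig) -> str:
    """Stable sha256 of the canonical JSON form of a configuration."""
    blob = json.dumps(config.model_dump(), sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()


def apply_override(config: RunConfig, path: str, value) -> RunConfig:
    """Return a copy of ``config`` with one dotted-path field overridden."""
    cfg = config.model_copy(deep=True)
    parts = path.split(".")
    obj = cfg
    for p in parts[:-1]:
        if not hasattr(obj, p):
            raise ValueError(f"unknown configuration path: {path}")
        obj = getattr(obj, p)
    if not hasattr(obj, parts[-1]):
        raise ValueError(f"unknown configuration path: {path}")
    setattr(obj, parts[-1], value)
    # re-validate the whole tree after mutation
    return RunConfig.model_validate(cfg.model_dump())
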