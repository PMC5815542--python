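"""End-to-end analysis: configuration → cohort traces → outcomes → ICERs.

Male and female cohorts are simulated separately against their own life
tables and combined at the outcome level with the cohort sex weights
(default 0.80/0.20).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cea import IncrementalResult, incremental
from .config import RunConfig, secondary_preset
from .economics import ArmOutcomes, accumulate, combine_outcomes
from .markov import ARMS, CohortTrace, run_cohort

__all__ = ["AnalysisResult", "run_arm", "run_analysis"]


@dataclass(frozen=True)
class AnalysisResult:
    """Full incremental analysis of hydrophilic-coated vs PVC."""

    config: RunConfig
    outcomes: dict  # arm -> combined ArmOutcomes
    outcomes_by_sex: dict  # (arm, sex) -> ArmOutcomes
    result: IncrementalResult
    traces: dict = field(repr=False, default_factory=dict)  # (arm, sex) -> CohortTrace


def run_arm(
    config: RunConfig, arm: str, life_tables: dict | None = None,
    keep_traces: bool = False,
):
    """Simulate one strategy for both sexes; returns (combined outcomes,
    per-sex outcomes dict, per-sex traces dict)."""
    if arm not in ARMS:
        raise ValueError(f"arm must be one of {ARMS}, got {arm!r}")
    params = config.model_parameters()
    costs = config.cost_schedule()
    utils = config.utility_schedule()
    tables = life_tables or config.build_life_tables()
    rate = config.economics.discount_rate_annual
    half_cycle = config.flags.half_cycle

    by_sex: dict[str, ArmOutcomes] = {}
    traces: dict[str, CohortTrace] = {}
    for sex in ("male", "female"):
        trace = run_cohort(params, arm, tables[sex])
        by_sex[sex] = accumulate(trace, costs, utils, rate, half_cycle=half_cycle)
        if keep_traces:
            traces[sex] = trace
    weights = [params.proportion_male, 1.0 - params.proportion_male]
    combined = combine_outcomes([by_sex["male"], by_sex["female"]], weights)
    return combined, by_sex, traces


def run_analysis(config: RunConfig, keep_traces: bool = False) -> AnalysisResult:
    """Run both arms under ``config`` and compare them.

    ``config.analysis == "secondary"`` applies the UTI-only preset (stones,
    urethral injury and urosepsis zeroed) before running.
    """
    cfg = secondary_preset(config) if config.analysis == "secondary" else config
    tables = cfg.build_life_tables()
    outcomes: dict[str, ArmOutcomes] = {}
    outcomes_by_sex: dict[tuple[str, str], ArmOutcomes] = {}
    traces: dict[tuple[str, str], CohortTrace] = {}
    for arm in ARMS:
        combined, by_sex, arm_traces = run_arm(
            cfg, arm, life_tables=tables, keep_traces=keep_traces
        )
        outcomes[arm] = combined
        for sex, oc in by_sex.items():
            outcomes_by_sex[(arm, sex)] = oc
        for sex, tr in arm_traces.items():
            traces[(arm, sex)] = tr
    result = incremental(
        outcomes["hydrophilic"],
        outcomes["pvc"],
        threshold=cfg.economics.threshold_per_qaly,
    )
    return AnalysisResult(
        config=cfg,
        outcomes=outcomes,
        outcomes_by_sex=outcomes_by_sex,
        result=result,
        traces=traces,
    )
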