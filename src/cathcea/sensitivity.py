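"""Deterministic one-way sensitivity analysis.

Each scenario re-runs the full pipeline with exactly one parameter changed
from the base configuration; results are reported as the ICER per QALY next
to the base case, with a tornado ordering by absolute deviation.

The built-in scenario set varies the three parameters the published analysis
probed: lubricant tubes per day (1 and 4 vs base 2), first-line antibiotic
resistance (16.5% and 45% vs base 34%), and the UTI treatment effect
(relative risks 0.74 and 0.47 vs base 0.84, i.e. 26% and 53% reductions).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import RunConfig, apply_override
from .pipeline import run_analysis

__all__ = [
    "Scenario",
    "DsaResult",
    "default_scenarios",
    "run_one_way",
    "tornado_order",
    "dsa_report",
    "plot_tornado",
]

BASE_CASE_NAME = "base_case"


@dataclass(frozen=True)
class Scenario:
    """One single-parameter override with a provenance note."""

    name: str
    overrides: dict  # dotted config path -> value; exactly one entry
    note: str = ""

    def __post_init__(self) -> None:
        if len(self.overrides) != 1:
            raise ValueError(
                f"scenario {self.name!r}: one-way analysis requires exactly "
                f"one override, got {len(self.overrides)}"
            )


@dataclass(frozen=True)
class DsaResult:
    scenario: str
    icer_per_qaly: float | None
    delta_cost: float
    delta_qaly: float
    is_base: bool
    note: str = ""


def default_scenarios() -> list[Scenario]:
    return [
        Scenario("tubes_per_day=4", {"costs.tubes_per_day": 4.0},
                 "single-use lubricant per regulatory guidance"),
        Scenario("tubes_per_day=1", {"costs.tubes_per_day": 1.0},
                 "assumed lower bound"),
        Scenario("resistance=16%", {"resistance.first_line": 0.165},
                 "conservative ciprofloxacin resistance"),
        Scenario("resistance=45%", {"resistance.first_line": 0.45},
                 "assumed upper bound"),
        Scenario("uti_reduction=26%", {"treatment_effect.uti": 0.74},
                 "literature-review estimate"),
        Scenario("uti_reduction=53%", {"treatment_effect.uti": 0.47},
                 "long-term community data"),
    ]


def run_one_way(
    base_config: RunConfig, scenarios: list[Scenario] | None = None
) -> list[DsaResult]:
    """Run the base case plus each single-override scenario.

    Returns the base case first, then one result per scenario in input order.
    """
    if scenarios is None:
        scenarios = default_scenarios()
    results = []
    base = run_analysis(base_config).result
    results.append(
        DsaResult(BASE_CASE_NAME, base.icer_per_qaly, base.delta_cost,
                  base.delta_qaly, is_base=True)
    )
    for sc in scenarios:
        (path, value), = sc.overrides.items()
        cfg = apply_override(base_config, path, value)
        r = run_analysis(cfg).result
        results.append(
            DsaResult(sc.name, r.icer_per_qaly, r.delta_cost, r.delta_qaly,
                      is_base=False, note=sc.note)
        )
    return results


def tornado_order(results: list[DsaResult]) -> list[DsaResult]:
    """Non-base results sorted by |ICER − base ICER| descending, ties by name."""
    base = [r for r in results if r.is_base]
    if not base:
        raise ValueError("results must include the base case")
    others = [r for r in results if not r.is_base]
    if not others:
        raise ValueError("at least one non-base scenario is required")
    base_icer = base[0].icer_per_qaly
    if base_icer is None:
        raise ValueError("base-case ICER is undefined")

    def dev(r: DsaResult) -> float:
        return abs((r.icer_per_qaly if r.icer_per_qaly is not None else float("inf")) - base_icer)

    return sorted(others, key=lambda r: (-dev(r), r.scenario))


def dsa_report(results: list[DsaResult]) -> pd.DataFrame:
    """Scenario table: parameter varied, ICER per QALY, deviation from base."""
    base_icer = next(r.icer_per_qaly for r in results if r.is_base)
    rows = [
        {
            "scenario": r.scenario,
            "icer_per_qaly": None if r.icer_per_qaly is None else round(r.icer_per_qaly),
            "deviation_from_base": None
            if (r.is_base or r.icer_per_qaly is None)
            else round(r.icer_per_qaly - base_icer),
            "note": r.note,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def plot_tornado(results: list[DsaResult], path) -> None:
    """Horizontal-bar tornado diagram of ICER deviations from base."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    base_icer = next(r.icer_per_qaly for r in results if r.is_base)
    ordered = tornado_order(results)[::-1]  # largest bar on top
    names = [r.scenario for r in ordered]
    devs = [r.icer_per_qaly - base_icer for r in ordered]
    fig, ax = plt.subplots(figsize=(7, 0.5 * len(names) + 1.5))
    ax.barh(names, devs, color=["#b2182b" if d > 0 else "#2166ac" for d in devs])
    ax.axvline(0.0, color="k", lw=0.8)
    ax.set_xlabel(f"ICER deviation from base case ({base_icer:,.0f} BRL/QALY)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
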