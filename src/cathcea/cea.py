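"""Incremental cost-effectiveness analysis between two strategies.

Computes Δcost, ΔQALY, ΔLYG, ΔUTI and the three incremental ratios
(BRL/QALY gained, BRL/LYG, BRL/UTI avoided) from full-precision arm
outcomes, with dominance classification and a willingness-to-pay
threshold verdict (default 147,000 BRL/QALY).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .economics import ArmOutcomes

__all__ = ["IncrementalResult", "incremental", "DEFAULT_THRESHOLD", "incremental_report"]

DEFAULT_THRESHOLD = 147_000.0  # BRL per QALY


@dataclass(frozen=True)
class IncrementalResult:
    """Incremental comparison of ``new`` vs ``comparator``.

    Ratio fields are ``None`` when the corresponding effect delta does not
    support a meaningful ratio (ΔQALY ≤ 0 for the QALY ICER, ΔUTI ≥ 0 for
    cost per UTI avoided), in which case ``dominance`` carries the verdict.
    """

    new_arm: str
    comparator_arm: str
    delta_cost: float
    delta_qaly: float
    delta_lyg: float
    delta_uti: float
    icer_per_qaly: float | None
    icer_per_lyg: float | None
    cost_per_uti_avoided: float | None
    dominance: str  # interior | dominant | dominated
    threshold: float
    cost_effective: bool


def incremental(
    new: ArmOutcomes,
    comparator: ArmOutcomes,
    threshold: float = DEFAULT_THRESHOLD,
) -> IncrementalResult:
    """Incremental analysis, deltas as new − comparator.

    Dominant: the new strategy costs no more and yields no fewer QALYs (and
    differs in at least one); dominated is the reverse.  ICERs are reported
    for interior comparisons; a dominant strategy is cost-effective at any
    threshold.
    """
    d_cost = new.cost - comparator.cost
    d_qaly = new.qalys - comparator.qalys
    d_lyg = new.lyg - comparator.lyg
    d_uti = new.uti_count - comparator.uti_count

    if d_cost <= 0 and d_qaly >= 0 and (d_cost != 0 or d_qaly != 0):
        dominance = "dominant"
    elif d_cost >= 0 and d_qaly <= 0 and (d_cost != 0 or d_qaly != 0):
        dominance = "dominated"
    else:
        dominance = "interior"

    icer_q = d_cost / d_qaly if d_qaly > 0 else None
    icer_l = d_cost / d_lyg if d_lyg > 0 else None
    cost_uti = d_cost / (-d_uti) if d_uti < 0 else None

    cost_effective = dominance == "dominant" or (
        dominance == "interior" and icer_q is not None and icer_q <= threshold
    )
    return IncrementalResult(
        new_arm=new.arm,
        comparator_arm=comparator.arm,
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        delta_lyg=d_lyg,
        delta_uti=d_uti,
        icer_per_qaly=icer_q,
        icer_per_lyg=icer_l,
        cost_per_uti_avoided=cost_uti,
        dominance=dominance,
        threshold=threshold,
        cost_effective=cost_effective,
    )


def incremental_report(
    new: ArmOutcomes, comparator: ArmOutcomes, result: IncrementalResult
) -> pd.DataFrame:
    """Side-by-side arm table with the incremental row, display-rounded
    (costs to whole BRL, effects to 3 decimals, UTIs to 2)."""

    def row(label, cost, qalys, lyg, uti):
        return {
            "strategy": label,
            "cost_brl": round(cost),
            "qalys": round(qalys, 3),
            "lyg": round(lyg, 3),
            "uti": round(uti, 2),
        }

    df = pd.DataFrame(
        [
            row(comparator.arm, comparator.cost, comparator.qalys,
                comparator.lyg, comparator.uti_count),
            row(new.arm, new.cost, new.qalys, new.lyg, new.uti_count),
            row("incremental", result.delta_cost, result.delta_qaly,
                result.delta_lyg, result.delta_uti),
        ]
    )
    df.attrs["icer_per_qaly"] = result.icer_per_qaly
    df.attrs["icer_per_lyg"] = result.icer_per_lyg
    df.attrs["cost_per_uti_avoided"] = result.cost_per_uti_avoided
    df.attrs["dominance"] = result.dominance
    df.attrs["cost_effective"] = result.cost_effective
    return df
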