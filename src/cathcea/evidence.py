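"""Evidence synthesis: per-study monthly UTI rates, relative risks, and the
patient-weighted pooled relative risk and pooled PVC rate that parameterize
the cohort model.

Pooling is the sample-size-weighted mean — per-study relative risks weighted
by the hydrophilic-arm N, and per-arm monthly rates weighted by that arm's N.
No formal meta-analysis machinery (random effects, heterogeneity) is
involved; the published model used only the N-weighted mean.

The packaged fixture (``table1_studies.csv``) carries the four trials the
model rests on: Cardenas 2011, Sarica 2010, Cardenas 2009 and De Ridder 2005.
For Cardenas 2011 the monthly rates are stored at full precision recovered
from the published patient-weighted products (54.49/114 and 50.30/105); the
2-decimal display of both is 0.48.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "StudyArm",
    "StudyRates",
    "PooledEvidence",
    "monthly_rate",
    "study_rr",
    "pool",
    "round_display",
    "load_study_table",
    "table1_studies",
    "pair_arms",
    "evidence_report",
]

CATHETER_TYPES = ("pvc", "hydrophilic")


def round_display(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, as the published tables do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class StudyArm:
    """One catheter arm of one published trial — the unit of pooling."""

    study_id: str
    catheter_type: str
    n_patients: int
    followup_months: float
    uti_incidence: float | None = None  # mean UTIs per patient over follow-up
    utis_per_month: float | None = None  # given directly when incidence absent

    def __post_init__(self) -> None:
        if self.catheter_type not in CATHETER_TYPES:
            raise ValueError(f"catheter_type must be one of {CATHETER_TYPES}")
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.followup_months <= 0:
            raise ValueError("followup_months must be positive")
        if self.uti_incidence is None and self.utis_per_month is None:
            raise ValueError(
                f"{self.study_id}/{self.catheter_type}: need uti_incidence "
                "or utis_per_month"
            )
        if self.utis_per_month is not None and self.utis_per_month < 0:
            raise ValueError("utis_per_month must be nonnegative")
        if self.uti_incidence is not None and self.uti_incidence < 0:
            raise ValueError("uti_incidence must be nonnegative")


def monthly_rate(arm: StudyArm) -> float:
    """UTIs per patient-month for one arm (unrounded).

    Uses the directly-reported monthly rate when present, otherwise
    incidence over follow-up.
    """
    if arm.utis_per_month is not None:
        return float(arm.utis_per_month)
    return float(arm.uti_incidence) / float(arm.followup_months)


def study_rr(hydro: StudyArm, pvc: StudyArm) -> float:
    """Relative risk of monthly UTI, hydrophilic over PVC, from unrounded rates."""
    if hydro.study_id != pvc.study_id:
        raise ValueError("arms must come from the same study")
    r_pvc = monthly_rate(pvc)
    if r_pvc == 0:
        raise ZeroDivisionError(
            f"{pvc.study_id}: relative risk undefined for zero PVC rate"
        )
    return monthly_rate(hydro) / r_pvc


@dataclass(frozen=True)
class StudyRates:
    pvc_rate: float
    hydro_rate: float
    rr: float  # unrounded
    rr_display: float  # 2-decimal, the value entering default pooling


@dataclass(frozen=True)
class PooledEvidence:
    per_study: Mapping[str, StudyRates]
    pooled_rr: float
    pooled_rr_unrounded: float
    pooled_pvc_monthly_rate: float
    weights_used: Mapping[str, int]  # hydrophilic-arm N per study
    pvc_n: Mapping[str, int]


def pair_arms(arms: Iterable[StudyArm]) -> list[tuple[StudyArm, StudyArm]]:
    """Group arms into (hydrophilic, pvc) pairs by study_id, input order kept."""
    by_study: dict[str, dict[str, StudyArm]] = {}
    order: list[str] = []
    for arm in arms:
        slot = by_study.setdefault(arm.study_id, {})
        if arm.catheter_type in slot:
            raise ValueError(f"duplicate {arm.catheter_type} arm for {arm.study_id}")
        slot[arm.catheter_type] = arm
        if arm.study_id not in order:
            order.append(arm.study_id)
    pairs = []
    for sid in order:
        slot = by_study[sid]
        if set(slot) != set(CATHETER_TYPES):
            raise ValueError(f"study {sid} lacks one of its two arms")
        pairs.append((slot["hydrophilic"], slot["pvc"]))
    return pairs


def pool(
    pairs: Iterable[tuple[StudyArm, StudyArm]], rounded_rr: bool = True
) -> PooledEvidence:
    """Patient-weighted pooling across studies.

    pooled RR = Σ RR_i · N_i(hydro) / Σ N_i(hydro); pooled PVC rate =
    Σ rate_i(pvc) · N_i(pvc) / Σ N_i(pvc).  With ``rounded_rr`` (default)
    the per-study RRs enter the weighted mean at their 2-decimal display
    precision, matching the published pooling; set False for full precision.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("at least one study is required")
    per_study: dict[str, StudyRates] = {}
    weights: dict[str, int] = {}
    pvc_n: dict[str, int] = {}
    num_r = num_u = den_rr = 0.0
    num_rate = den_rate = 0.0
    for hydro, pvc in pairs:
        rr = study_rr(hydro, pvc)
        sr = StudyRates(
            pvc_rate=monthly_rate(pvc),
            hydro_rate=monthly_rate(hydro),
            rr=rr,
            rr_display=round_display(rr),
        )
        per_study[hydro.study_id] = sr
        weights[hydro.study_id] = hydro.n_patients
        pvc_n[hydro.study_id] = pvc.n_patients
        num_r += sr.rr_display * hydro.n_patients
        num_u += sr.rr * hydro.n_patients
        den_rr += hydro.n_patients
        num_rate += sr.pvc_rate * pvc.n_patients
        den_rate += pvc.n_patients
    pooled_unrounded = num_u / den_rr
    pooled = (num_r / den_rr) if rounded_rr else pooled_unrounded
    return PooledEvidence(
        per_study=per_study,
        pooled_rr=pooled,
        pooled_rr_unrounded=pooled_unrounded,
        pooled_pvc_monthly_rate=num_rate / den_rate,
        weights_used=weights,
        pvc_n=pvc_n,
    )


def load_study_table(path) -> list[StudyArm]:
    """Read the delimited study-data dialect (empty cells mean absent)."""
    df = pd.read_csv(path)
    required = {
        "study_id", "catheter_type", "n_patients",
        "uti_incidence", "followup_months", "utis_per_month",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"study table missing columns: {sorted(missing)}")
    arms = []
    for row in df.itertuples(index=False):
        arms.append(
            StudyArm(
                study_id=str(row.study_id),
                catheter_type=str(row.catheter_type),
                n_patients=int(row.n_patients),
                followup_months=float(row.followup_months),
                uti_incidence=None if pd.isna(row.uti_incidence) else float(row.uti_incidence),
                utis_per_month=None if pd.isna(row.utis_per_month) else float(row.utis_per_month),
            )
        )
    return arms


def table1_studies() -> list[StudyArm]:
    """The packaged four-trial evidence base."""
    with resources.as_file(
        resources.files("cathcea").joinpath("data/table1_studies.csv")
    ) as p:
        return load_study_table(p)


def evidence_report(pooled: PooledEvidence) -> pd.DataFrame:
    """Tabular echo of the evidence base: rates, weighted products and RRs.

    ``weighted_average`` is N × monthly rate (the patient-weighted product
    entering the pooled PVC rate); displayed values are rounded to 2 decimals.
    """
    rows = []
    for sid, sr in pooled.per_study.items():
        n_h = pooled.weights_used[sid]
        n_p = pooled.pvc_n[sid]
        rows.append(
            {
                "study_id": sid,
                "pvc_n": n_p,
                "pvc_rate": round_display(sr.pvc_rate),
                "pvc_weighted_average": round_display(sr.pvc_rate * n_p),
                "hydro_n": n_h,
                "hydro_rate": round_display(sr.hydro_rate),
                "hydro_weighted_average": round_display(sr.hydro_rate * n_h),
                "rr": sr.rr_display,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["pooled_rr"] = round_display(pooled.pooled_rr)
    df.attrs["pooled_pvc_monthly_rate"] = round_display(
        pooled.pooled_pvc_monthly_rate, 4
    )
    return df
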