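"""Synthetic catheter-trial generator.

Produces per-patient UTI counts with the Poisson structure the evidence
pooling stage assumes (counts with mean ``rate × months``), so the
rate-recovery behaviour of the pooling formulas can be tested without any
published individual-level data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SimulatedTrial", "simulate_trial", "write_trial", "read_trial"]


@dataclass(frozen=True)
class SimulatedTrial:
    arm_label: str
    n_patients: int
    months: float
    event_counts: np.ndarray = field(repr=False)
    seed: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.event_counts, dtype=np.int64)
        object.__setattr__(self, "event_counts", counts)
        if len(counts) != self.n_patients:
            raise ValueError("event_counts length must equal n_patients")
        if np.any(counts < 0):
            raise ValueError("event counts must be nonnegative")

    @property
    def empirical_rate(self) -> float:
        """Observed UTIs per patient-month."""
        return float(self.event_counts.sum()) / (self.n_patients * self.months)


def simulate_trial(
    rate: float, n_patients: int, months: float, seed: int, arm_label: str = "arm"
) -> SimulatedTrial:
    """Draw per-patient UTI counts ~ Poisson(rate × months), reproducibly.

    ``rate`` is the true UTIs per patient-month. Uses numpy's PCG64
    generator seeded with ``seed``.
    """
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if months <= 0:
        raise ValueError("months must be positive")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam=rate * months, size=n_patients)
    return SimulatedTrial(arm_label, int(n_patients), float(months), counts, int(seed))


def write_trial(trial: SimulatedTrial, path) -> None:
    """Write ``patient_id,arm,months,uti_count`` delimited text."""
    df = pd.DataFrame(
        {
            "patient_id": np.arange(trial.n_patients),
            "arm": trial.arm_label,
            "months": trial.months,
            "uti_count": trial.event_counts,
        }
    )
    df.to_csv(path, index=False)


def read_trial(path, seed: int = -1) -> SimulatedTrial:
    """Read a trial file written by :func:`write_trial`.

    The seed is not stored in the file; pass it if known (``-1`` = unknown).
    """
    df = pd.read_csv(path)
    arms = df["arm"].unique()
    if len(arms) != 1:
        raise ValueError("trial file must contain a single arm")
    months = df["months"].unique()
    if len(months) != 1:
        raise ValueError("trial file must contain a single follow-up duration")
    return SimulatedTrial(
        arm_label=str(arms[0]),
        n_patients=len(df),
        months=float(months[0]),
        event_counts=df["uti_count"].to_numpy(dtype=np.int64),
        seed=int(seed),
    )
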