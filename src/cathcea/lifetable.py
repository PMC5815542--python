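"""Annual life tables and the probability conversions the monthly model needs.

The cohort engine runs in monthly cycles against an annual life table of
death probabilities ``q_x``.  Because no national table ships with the
package, a Gompertz–Makeham generator provides synthetic tables whose adult
life expectancy is broadly consistent with Brazil in the mid-2010s (see the
frozen defaults in :data:`DEFAULT_GM_PARAMS`).  These are stand-ins for an
official table, not reproductions of one.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "gompertz_makeham_life_table",
    "life_expectancy",
    "annual_to_monthly_prob",
    "read_life_table",
    "write_life_table",
    "DEFAULT_GM_PARAMS",
]

VALID_SEXES = ("male", "female", "combined")

#: Frozen Gompertz–Makeham parameters (a: background hazard /yr, b: senescent
#: hazard scale /yr, c: senescent growth per year of age) chosen once so that
#: life expectancy at birth lands near 71.4 y (male) and 78.6 y (female),
#: emulating Brazilian 2014 mortality levels.  Synthetic stand-ins.
DEFAULT_GM_PARAMS = {
    "male": {"a": 1.3e-3, "b": 7.0e-5, "c": 1.092},
    "female": {"a": 6.0e-4, "b": 3.8e-5, "c": 1.094},
}
DEFAULT_AGE_END = 110


@dataclass(frozen=True)
class LifeTable:
    """Sex-specific annual death probabilities from ``age_start`` to a
    terminal age at which death is certain.

    ``q_annual[i]`` is the probability of dying within the year for a person
    of exact age ``age_start + i``; the final entry must be 1.
    """

    sex: str
    age_start: int
    q_annual: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        q = np.asarray(self.q_annual, dtype=float)
        object.__setattr__(self, "q_annual", q)
        if self.sex not in VALID_SEXES:
            raise ValueError(f"sex must be one of {VALID_SEXES}, got {self.sex!r}")
        if q.ndim != 1 or q.size == 0:
            raise ValueError("q_annual must be a non-empty 1-d sequence")
        if np.any(q < 0) or np.any(q > 1):
            raise ValueError("all q_annual entries must lie in [0, 1]")
        if q[-1] != 1.0:
            raise ValueError("terminal-age death probability must equal 1")

    @property
    def terminal_age(self) -> int:
        return self.age_start + len(self.q_annual) - 1

    def q_at(self, age: int) -> float:
        """Annual death probability for integer ``age`` (clamped at terminal)."""
        if age < self.age_start or age > self.terminal_age:
            raise ValueError(
                f"age {age} outside table range "
                f"[{self.age_start}, {self.terminal_age}]"
            )
        return float(self.q_annual[age - self.age_start])


def gompertz_makeham_life_table(
    a: float,
    b: float,
    c: float,
    age_start: int = 0,
    age_end: int = DEFAULT_AGE_END,
    sex: str = "combined",
) -> LifeTable:
    """Build an annual life table from a Gompertz–Makeham hazard.

    The annual hazard at age x is ``a + b * c**x`` (a: age-independent
    background component, b·c**x: senescent component), so
    ``q_x = 1 - exp(-(a + b * c**x))``.  The terminal entry is forced to 1.
    """
    if a < 0 or b < 0:
        raise ValueError("hazard parameters a and b must be nonnegative")
    if c < 1:
        raise ValueError("senescent growth factor c must be >= 1")
    if age_start >= age_end:
        raise ValueError("age_start must be below age_end")
    ages = np.arange(age_start, age_end + 1, dtype=float)
    q = 1.0 - np.exp(-(a + b * c**ages))
    q[-1] = 1.0
    return LifeTable(sex=sex, age_start=int(age_start), q_annual=q)


def annual_to_monthly_prob(q: float) -> float:
    """Convert an annual death probability to the equivalent monthly one,
    assuming a constant hazard within the year: ``p = 1 - (1-q)**(1/12)``.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"annual probability must lie in [0, 1], got {q}")
    return 1.0 - (1.0 - q) ** (1.0 / 12.0)


def life_expectancy(table: LifeTable, age: int) -> float:
    """Remaining life expectancy at integer ``age`` in years.

    Computed at monthly resolution from the survival product, with the
    mid-period convention (deaths occur on average halfway through each
    month, i.e. each month contributes the trapezoid of survival).  This is
    the convention the cohort engine's half-cycle-corrected person-time
    accounting reproduces.
    """
    if age < table.age_start or age > table.terminal_age:
        raise ValueError(
            f"age {age} outside table range [{table.age_start}, {table.terminal_age}]"
        )
    e = 0.0
    surv = 1.0
    for yr in range(age, table.terminal_age + 1):
        p_m = annual_to_monthly_prob(table.q_at(yr))
        for _ in range(12):
            nxt = surv * (1.0 - p_m)
            e += (surv + nxt) / 2.0 / 12.0
            surv = nxt
        if surv < 1e-15:
            break
    return e


# ---------------------------------------------------------------------------
# file I/O — delimited text, round-trips bit-exactly at 12 significant digits

def write_life_table(table: LifeTable, path) -> None:
    """Write ``age,sex,q_annual`` delimited text (q at 12 significant digits)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_serialize(table))


def _serialize(table: LifeTable) -> str:
    buf = io.StringIO()
    buf.write("age,sex,q_annual\n")
    for i, q in enumerate(table.q_annual):
        buf.write(f"{table.age_start + i},{table.sex},{q:.12g}\n")
    return buf.getvalue()


def read_life_table(path) -> LifeTable:
    df = pd.read_csv(path, dtype={"age": int, "sex": str, "q_annual": float})
    required = {"age", "sex", "q_annual"}
    if set(df.columns) != required:
        raise ValueError(f"life-table file must have columns {sorted(required)}")
    sexes = df["sex"].unique()
    if len(sexes) != 1:
        raise ValueError("life-table file must contain a single sex")
    df = df.sort_values("age").reset_index(drop=True)
    ages = df["age"].to_numpy()
    if not np.array_equal(ages, np.arange(ages[0], ages[0] + len(ages))):
        raise ValueError("ages must be contiguous")
    return LifeTable(sex=str(sexes[0]), age_start=int(ages[0]),
                     q_annual=df["q_annual"].to_numpy(dtype=float))
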