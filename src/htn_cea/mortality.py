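"""Background (non-cardiovascular) mortality.

The cohort model needs the annual probability of dying from causes other
than cardiovascular disease at each age from 65 up.  National life
tables for the study setting are not distributed with the package, so a
parametric generator stands in: a Gompertz all-cause hazard

    h(x) = a * exp(b * (x - 65))

from which a constant cardiovascular fraction is removed multiplicatively,

    qx = (1 - exp(-h(x))) * (1 - cv_fraction),

capped at 1.  The defaults (a=0.013, b=0.095, cv_fraction=0.30) give a
remaining all-cause life expectancy at 65 of about 18 years, typical of
the urban middle-class population the model describes.  Cardiovascular
deaths enter the model through the acute-event pathway, never through
this table.

A reader for externally supplied tables (CSV, columns ``age,qx``) is
also provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .distributions import ValidationError

__all__ = ["LifeTable", "synthetic_life_table", "load_life_table", "q_noncv",
           "life_expectancy"]

START_AGE = 65


@dataclass(frozen=True)
class LifeTable:
    """Annual non-cardiovascular death probabilities for ages 65..max_age.

    ``qx[max_age - 65]`` is 1: the table's last age is an absorbing cap.
    """

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.size == 0 or ages[0] != START_AGE:
            raise ValidationError(f"life table must start at age {START_AGE}")
        if not np.array_equal(ages, np.arange(ages[0], ages[-1] + 1)):
            raise ValidationError("life table ages must be consecutive integers")
        if qx.shape != ages.shape:
            raise ValidationError("ages and qx must have equal length")
        if ((qx < 0) | (qx > 1)).any():
            raise ValidationError("qx values must lie in [0, 1]")
        if (np.diff(qx) < -1e-12).any():
            raise ValidationError("qx must be non-decreasing in age")
        if qx[-1] != 1.0:
            raise ValidationError("qx at the terminal age must be 1")

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def lookup(self, age) -> np.ndarray:
        """Vectorised qx lookup; ages beyond the table return 1."""
        idx = np.clip(np.asarray(age, dtype=int) - START_AGE, None, self.ages.size - 1)
        if (idx < 0).any():
            raise ValidationError(f"age below {START_AGE}")
        return self.qx[idx]


def synthetic_life_table(a: float = 0.013, b: float = 0.095,
                         cv_fraction: float = 0.30, max_age: int = 100) -> LifeTable:
    """Gompertz life table with the cardiovascular fraction removed."""
    if a <= 0 or b <= 0:
        raise ValidationError("Gompertz parameters a, b must be > 0")
    if not (0.0 <= cv_fraction < 1.0):
        raise ValidationError("cv_fraction must lie in [0, 1)")
    if max_age <= START_AGE:
        raise ValidationError("max_age must exceed 65")
    ages = np.arange(START_AGE, max_age + 1)
    h = a * np.exp(b * (ages - START_AGE))
    qx = np.minimum(1.0, (1.0 - np.exp(-h)) * (1.0 - cv_fraction))
    qx = np.maximum.accumulate(qx)  # guard monotonicity at the cap
    qx[-1] = 1.0
    return LifeTable(ages=ages, qx=qx)


def load_life_table(path: Union[str, Path]) -> LifeTable:
    """Read a life table CSV with columns ``age, qx``."""
    df = pd.read_csv(path)
    if not {"age", "qx"}.issubset(df.columns):
        raise ValidationError("life table CSV must have columns 'age' and 'qx'")
    df = df.sort_values("age")
    return LifeTable(ages=df["age"].to_numpy(), qx=df["qx"].to_numpy())


def save_life_table(lt: LifeTable, path: Union[str, Path]) -> None:
    pd.DataFrame({"age": lt.ages, "qx": lt.qx}).to_csv(path, index=False)


def q_noncv(lt: LifeTable, age) -> float:
    """Annual probability of non-cardiovascular death at ``age``."""
    return float(lt.lookup(age)) if np.isscalar(age) else lt.lookup(age)


def life_expectancy(lt: LifeTable, start_age: int = START_AGE) -> float:
    """Expected whole years survived from ``start_age`` under the table alone.

    Uses the same convention as the cohort engine's life-year reward: one
    year credited per completed year, none in the year of death.  Serves
    as the closed-form oracle for the zero-cardiovascular-risk cohort.
    """
    q = lt.lookup(np.arange(start_age, lt.max_age))
    surv = np.cumprod(1.0 - q)
    return float(surv.sum())
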