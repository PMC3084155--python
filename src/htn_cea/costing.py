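"""Micro-costing: programme accounting ledger and per-cycle model costs.

Two layers live here.  The accounting layer reproduces the programme's
bottom-up resource ledger: each line item is unit cost times annual
quantity, capital goods are annuitised to an equivalent annual cost over
a 5-year life at 5%, and category subtotals are divided by the covered
population to give per-patient figures.  The model layer computes the
per-cycle treatment cost and the acute-event episode cost consumed by
the cohort engine; those use the sampled model inputs, not the ledger.

All amounts are 2010 International Dollars.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .distributions import ValidationError
from .params import StrategyCostComponents

__all__ = [
    "CATEGORIES",
    "LedgerItem",
    "CostBreakdown",
    "equivalent_annual_cost",
    "read_ledger",
    "packaged_ledger",
    "compute_ledger",
    "annual_treatment_cost",
    "event_episode_cost",
    "fit_lognormal",
]

#: programme-level categories are whole-programme annual totals;
#: per-patient categories are already expressed per patient-year.
PROGRAMME_LEVEL = ("labour", "capital", "land", "resource")
PER_PATIENT = ("overhead", "visit", "consumption")
CATEGORIES = PROGRAMME_LEVEL + PER_PATIENT

DEFAULT_CAPITAL_LIFETIME = 5.0
DEFAULT_CAPITAL_RATE = 0.05


@dataclass(frozen=True)
class LedgerItem:
    """One line of the resource ledger.

    ``quantity`` is the annual quantity (hours, units, m2-months, calls,
    visits ...); for direct annual amounts (software licences, drug
    consumption) quantity is 1 and ``unit_cost`` carries the amount.
    Capital items are annuitised with ``capital_lifetime`` years at
    ``capital_rate``.
    """

    name: str
    category: str
    unit_cost: float
    quantity: float
    strategy: str = "programme"
    group: Optional[str] = None
    capital_lifetime: float = DEFAULT_CAPITAL_LIFETIME
    capital_rate: float = DEFAULT_CAPITAL_RATE

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown ledger category {self.category!r}")
        if self.unit_cost < 0 or self.quantity < 0:
            raise ValidationError(f"negative cost/quantity in ledger item {self.name!r}")

    @property
    def annual_cost(self) -> float:
        outlay = self.unit_cost * self.quantity
        if self.category == "capital":
            return equivalent_annual_cost(outlay, self.capital_lifetime, self.capital_rate)
        return outlay


@dataclass
class CostBreakdown:
    """Category subtotals of one strategy's ledger.

    ``category_totals`` for programme-level categories are whole-programme
    Int$/year, converted to per-patient by dividing by ``population_size``;
    per-patient categories (overhead, visits, consumption) are already
    Int$/patient-year.
    """

    population_size: int
    category_totals: dict = field(default_factory=dict)
    group_totals: dict = field(default_factory=dict)

    @property
    def programme_total(self) -> float:
        return sum(self.category_totals.get(c, 0.0) for c in PROGRAMME_LEVEL)

    @property
    def programme_per_patient(self) -> float:
        return self.programme_total / self.population_size

    def per_patient(self, category: str) -> float:
        v = self.category_totals.get(category, 0.0)
        return v / self.population_size if category in PROGRAMME_LEVEL else v

    @property
    def annual_total_per_patient(self) -> float:
        return self.programme_per_patient + sum(
            self.category_totals.get(c, 0.0) for c in PER_PATIENT
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"category": c, "total": self.category_totals.get(c, 0.0),
             "per_patient": self.per_patient(c)}
            for c in CATEGORIES
        ]
        rows.append({"category": "programme_total", "total": self.programme_total,
                     "per_patient": self.programme_per_patient})
        rows.append({"category": "annual_total_per_patient", "total": np.nan,
                     "per_patient": self.annual_total_per_patient})
        return pd.DataFrame(rows)


def equivalent_annual_cost(capital_outlay: float, lifetime: float, rate: float) -> float:
    """Annuitise a capital outlay over its useful life.

    Uses the annuity-due convention (payments at period start), the one
    under which the published capital rows reproduce::

        EAC = outlay / AF,   AF = [(1 - (1+r)^-n) / r] * (1+r)

    with AF = n when the rate is zero.
    """
    if capital_outlay < 0:
        raise ValidationError("capital outlay must be >= 0")
    if lifetime < 1:
        raise ValidationError("capital lifetime must be >= 1 year")
    if rate < 0:
        raise ValidationError("discount rate must be >= 0")
    if rate < 1e-12:  # limit r -> 0; avoids catastrophic cancellation
        af = lifetime
    else:
        af = (1.0 - (1.0 + rate) ** -lifetime) / rate * (1.0 + rate)
    return capital_outlay / af


def read_ledger(path: Union[str, Path]) -> list[LedgerItem]:
    """Read a ledger CSV (columns: strategy,item,category,group,unit_cost,quantity)."""
    df = pd.read_csv(path, comment="#")
    required = {"strategy", "item", "category", "unit_cost", "quantity"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"ledger missing columns {sorted(missing)}")
    items = []
    for _, row in df.iterrows():
        group = row.get("group")
        items.append(LedgerItem(
            name=row["item"], category=row["category"],
            unit_cost=float(row["unit_cost"]), quantity=float(row["quantity"]),
            strategy=row["strategy"],
            group=None if pd.isna(group) else str(group),
        ))
    return items


def packaged_ledger() -> list[LedgerItem]:
    """The published programme/usual-care resource ledger shipped with the package."""
    ref = resources.files("htn_cea").joinpath("data/cost_ledger.csv")
    with resources.as_file(ref) as path:
        return read_ledger(path)


def compute_ledger(items: Iterable[LedgerItem], population_size: int,
                   strategy: str = "programme") -> CostBreakdown:
    """Aggregate ledger items for one strategy into category subtotals."""
    if population_size <= 0:
        raise ValidationError("population_size must be > 0")
    bd = CostBreakdown(population_size=population_size)
    for it in items:
        if it.strategy != strategy:
            continue
        bd.category_totals[it.category] = (
            bd.category_totals.get(it.category, 0.0) + it.annual_cost
        )
        if it.group:
            bd.group_totals[it.group] = bd.group_totals.get(it.group, 0.0) + it.annual_cost
    return bd


def annual_treatment_cost(c: StrategyCostComponents, first_cycle: bool = False) -> float:
    """Annual per-patient treatment cost charged to everyone alive at cycle start.

    Drug coverage scales drug cost only (it is the payer's share of drug
    spending); visits carry both the visit fee and the per-visit overhead.
    The one-off diagnostic work-up is added in the entry cycle.
    """
    cost = (
        c.drug_cost_year * c.drug_coverage
        + c.test_cost_year
        + c.programme_fee_year
        + c.n_visits_year * (c.visit_cost + c.overhead_per_visit)
        + c.ambulance_cost_year
    )
    if first_cycle:
        cost += c.first_year_test_cost
    return cost


def event_episode_cost(assisted: bool, c: StrategyCostComponents) -> float:
    """Hospital cost of one acute cardiovascular event episode.

    Charged only when the patient receives hospital attention; unassisted
    events (including sudden deaths) incur no hospital expenditure.
    """
    return c.event_hospital_cost if assisted else 0.0


def fit_lognormal(samples) -> tuple[float, float]:
    """Fit a lognormal law to positive cost samples.

    Returns the mean and sd (ddof=1) of the log-transformed samples — the
    (mu, sigma) parameterisation used throughout the model.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 samples")
    if (x <= 0).any():
        raise ValidationError("lognormal fit requires strictly positive samples")
    logs = np.log(x)
    return float(logs.mean()), float(logs.std(ddof=1))
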