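"""Model parameters: base-case values, sampling laws, file round-trip.

The decision model compares two strategies — a comprehensive hypertension
management programme and usual primary care — in a cohort of hypertensive
patients aged 65 or older.  Every input is a :class:`DistributionSpec`
holding the base-case value and the law used by the probabilistic
sensitivity analysis.  All monetary amounts are 2010 International
Dollars (Int$); probabilities are annual.

The parameter set is organised in three blocks:

* per-strategy cost/utilisation inputs and the strategy's hazard ratio
  on cardiovascular event risk (relative to the untreated reference
  population),
* common inputs shared by both strategies: unit costs, the reference
  event risks by age band and risk stratum, the acute-event pathway
  probabilities, the cohort composition, and the starting age,
* structural/economic settings (discount rate, willingness-to-pay
  threshold, horizon, iteration counts) that are never sampled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .distributions import DistributionSpec, ValidationError, fixed, lognormal, normal, uniform

__all__ = [
    "SchemaError",
    "ValidationError",
    "StrategyInputs",
    "CommonInputs",
    "EconSettings",
    "ParameterSet",
    "StrategyCostComponents",
    "EventRiskTable",
    "AcuteEventModel",
    "base_case",
    "load_parameters",
    "save_parameters",
    "validate_distributions",
]

SCHEMA_VERSION = 1

BAND_SWITCH_AGE = 75  # 65-74 vs 75+ age bands


class SchemaError(KeyError):
    """A parameter file is missing a required key or has the wrong shape."""


# ---------------------------------------------------------------------------
# Distribution blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrategyInputs:
    """Per-strategy sampled inputs (costs in Int$, visits per year)."""

    drug_cost_year: DistributionSpec
    test_cost_year: DistributionSpec
    programme_fee_year: DistributionSpec
    n_visits_year: DistributionSpec
    hazard_ratio: DistributionSpec
    #: alternative uniform law for the hazard ratio used in scenario mode
    #: (replaces the normal draw; never sampled simultaneously with it)
    hazard_ratio_scenario: Optional[DistributionSpec] = None


@dataclass(frozen=True)
class CommonInputs:
    """Inputs shared by both strategies; sampled once per PSA iteration."""

    visit_cost: DistributionSpec
    overhead_per_visit: DistributionSpec
    ambulance_cost_year: DistributionSpec
    drug_coverage: DistributionSpec
    event_hospital_cost: DistributionSpec
    first_year_test_cost: DistributionSpec
    # annual cardiovascular event risk in the untreated reference population
    risk_int_65_74: DistributionSpec
    risk_int_75plus: DistributionSpec
    risk_high_65_74: DistributionSpec
    risk_high_75plus: DistributionSpec
    # acute-event pathway
    p_sudden_death: DistributionSpec
    p_unrecognized: DistributionSpec
    cfr_assisted_65_74: DistributionSpec
    cfr_assisted_75plus: DistributionSpec
    cfr_unassisted_65_74: DistributionSpec
    cfr_unassisted_75plus: DistributionSpec
    # cohort composition
    p_start_intermediate: DistributionSpec
    start_age: DistributionSpec


@dataclass(frozen=True)
class EconSettings:
    """Structural settings: never sampled by the PSA.

    ``discount_rate`` applies identically to costs and life-years.  The
    willingness-to-pay threshold of 45,000 Int$/LYG corresponds to three
    times the 2010 per-capita GDP of the study setting.  Behavioural
    switches expose modelling conventions that the base case adopts:
    no half-cycle correction, zero life-years credited in the year of
    death, drug costs scaled by the payer's coverage fraction, and the
    full annual treatment cost charged to everyone alive at cycle start.
    """

    discount_rate: float = 0.05
    wtp_threshold: float = 45_000.0
    wtp_grid: tuple = tuple(range(0, 100_001, 1_000))
    max_age: int = 100
    cycle_length: float = 1.0
    psa_iterations: int = 100_000
    seed: Optional[int] = None
    population_size: int = 30_000
    scenario_rates: tuple = (0.0, 0.03, 0.05, 0.07, 0.12)
    # modelling-convention switches
    half_cycle_correction: bool = False
    credit_half_year_at_death: bool = False
    apply_drug_coverage: bool = True
    #: if true, the PSA redraws the starting age and starting stratum mix
    #: each iteration; by default they are structural (tornado-only), which
    #: is the reading consistent with the published uncertainty intervals.
    sample_cohort_composition: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.discount_rate <= 0.2):
            raise ValidationError(f"discount_rate {self.discount_rate} outside [0, 0.2]")
        if self.max_age <= 65:
            raise ValidationError("max_age must exceed 65")
        if self.population_size < 0:
            raise ValidationError("population_size must be >= 0")


@dataclass(frozen=True)
class ParameterSet:
    """Complete model input set for both strategies."""

    usual: StrategyInputs
    programme: StrategyInputs
    common: CommonInputs
    econ: EconSettings = field(default_factory=EconSettings)

    # -- dotted-path access (used by one-way sensitivity sweeps) ----------
    def get_spec(self, name: str) -> DistributionSpec:
        block, _, fld = name.partition(".")
        try:
            return getattr(getattr(self, block), fld)
        except AttributeError as exc:
            raise KeyError(f"unknown parameter {name!r}") from exc

    def replace_spec(self, name: str, spec: DistributionSpec) -> "ParameterSet":
        block, _, fld = name.partition(".")
        if not hasattr(self, block) or not hasattr(getattr(self, block), fld):
            raise KeyError(f"unknown parameter {name!r}")
        new_block = dataclasses.replace(getattr(self, block), **{fld: spec})
        return dataclasses.replace(self, **{block: new_block})

    def sampled_names(self) -> list[str]:
        """Dotted names of every non-fixed parameter, in canonical draw order."""
        out = []
        for block in ("common", "usual", "programme"):
            obj = getattr(self, block)
            for f in dataclasses.fields(obj):
                spec = getattr(obj, f.name)
                if isinstance(spec, DistributionSpec) and not spec.is_fixed:
                    out.append(f"{block}.{f.name}")
        return out

    def all_fixed(self) -> "ParameterSet":
        """Copy with every distribution collapsed to its base-case value."""
        ps = self
        for name in self.sampled_names():
            ps = ps.replace_spec(name, ps.get_spec(name).with_base(ps.get_spec(name).base))
        return ps


# ---------------------------------------------------------------------------
# Numeric views consumed by the cohort engine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrategyCostComponents:
    """Numeric per-strategy cost components (Int$ unless noted)."""

    drug_cost_year: float
    test_cost_year: float
    programme_fee_year: float
    n_visits_year: float
    visit_cost: float
    overhead_per_visit: float
    ambulance_cost_year: float
    drug_coverage: float
    first_year_test_cost: float
    event_hospital_cost: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValidationError(f"{f.name} must be >= 0, got {v}")
        if not (0.0 <= self.drug_coverage <= 1.0):
            raise ValidationError(f"drug_coverage {self.drug_coverage} outside [0, 1]")


@dataclass(frozen=True)
class EventRiskTable:
    """Annual cardiovascular event probability in the untreated reference
    population, by age band (65-74 / 75+) and risk stratum."""

    int_65_74: float
    int_75plus: float
    high_65_74: float
    high_75plus: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"event risk {f.name}={v} outside [0, 1]")

    def p_ref(self, age: float, stratum: str) -> float:
        old = age >= BAND_SWITCH_AGE
        if stratum == "intermediate":
            return self.int_75plus if old else self.int_65_74
        if stratum == "high":
            return self.high_75plus if old else self.high_65_74
        raise ValidationError(f"unknown stratum {stratum!r}")


@dataclass(frozen=True)
class AcuteEventModel:
    """Acute cardiovascular event sub-tree probabilities.

    A fraction ``p_sudden_death`` of events is immediately fatal with no
    opportunity for care; of the remainder, ``p_unrecognized`` receive no
    hospital attention (asymptomatic or atypical presentations).  Case
    fatality within the year depends on hospital assistance and age band.
    """

    p_sudden_death: float
    p_unrecognized: float
    cfr_assisted_65_74: float
    cfr_assisted_75plus: float
    cfr_unassisted_65_74: float
    cfr_unassisted_75plus: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{f.name}={v} outside [0, 1]")
        if self.cfr_unassisted_65_74 < self.cfr_assisted_65_74 or (
            self.cfr_unassisted_75plus < self.cfr_assisted_75plus
        ):
            raise ValidationError("unassisted case fatality must be >= assisted")

    def cfr(self, assisted: bool, age: float) -> float:
        old = age >= BAND_SWITCH_AGE
        if assisted:
            return self.cfr_assisted_75plus if old else self.cfr_assisted_65_74
        return self.cfr_unassisted_75plus if old else self.cfr_unassisted_65_74


def strategy_cost_components(ps: ParameterSet, strategy: str) -> StrategyCostComponents:
    """Numeric cost components for one strategy at the set's current bases."""
    s = getattr(ps, strategy)
    c = ps.common
    return StrategyCostComponents(
        drug_cost_year=s.drug_cost_year.base,
        test_cost_year=s.test_cost_year.base,
        programme_fee_year=s.programme_fee_year.base,
        n_visits_year=s.n_visits_year.base,
        visit_cost=c.visit_cost.base,
        overhead_per_visit=c.overhead_per_visit.base,
        ambulance_cost_year=c.ambulance_cost_year.base,
        drug_coverage=c.drug_coverage.base if ps.econ.apply_drug_coverage else 1.0,
        first_year_test_cost=c.first_year_test_cost.base,
        event_hospital_cost=c.event_hospital_cost.base,
    )


def event_risk_table(ps: ParameterSet) -> EventRiskTable:
    c = ps.common
    return EventRiskTable(
        int_65_74=c.risk_int_65_74.base,
        int_75plus=c.risk_int_75plus.base,
        high_65_74=c.risk_high_65_74.base,
        high_75plus=c.risk_high_75plus.base,
    )


def acute_event_model(ps: ParameterSet) -> AcuteEventModel:
    c = ps.common
    return AcuteEventModel(
        p_sudden_death=c.p_sudden_death.base,
        p_unrecognized=c.p_unrecognized.base,
        cfr_assisted_65_74=c.cfr_assisted_65_74.base,
        cfr_assisted_75plus=c.cfr_assisted_75plus.base,
        cfr_unassisted_65_74=c.cfr_unassisted_65_74.base,
        cfr_unassisted_75plus=c.cfr_unassisted_75plus.base,
    )


# ---------------------------------------------------------------------------
# Base case
# ---------------------------------------------------------------------------

def base_case(econ: Optional[EconSettings] = None, visits: str = "ledger") -> ParameterSet:
    """The published base-case parameter set.

    Costs are 2010 Int$; lognormal laws are parameterised by the mean and
    sd of the natural log, uniform laws by their bounds (base = midpoint
    for symmetric intervals).  Hazard ratios multiply the reference event
    risk; normal hazard-ratio draws are truncated to (0, 1.5].

    ``visits`` selects which strategy carries the higher visit-count law.
    The model's two published input tables disagree: the per-strategy
    variable table prints the higher count (lognormal(1.68, 0.89), base
    7.68/yr) under usual care, while the costing ledger records more
    visits — and a higher per-patient annual total — for the programme,
    and only the latter reading reproduces the published base-case and
    probabilistic results (usual care least costly, positive incremental
    cost).  ``"ledger"`` (default) assigns the higher law to the
    programme; ``"printed"`` follows the variable table literally.
    """
    if visits not in ("ledger", "printed"):
        raise ValidationError("visits must be 'ledger' or 'printed'")
    visits_high = lognormal(1.68, 0.89, base=7.68)
    visits_low = lognormal(1.16, 0.85, base=4.72)
    usual_visits, programme_visits = (
        (visits_low, visits_high) if visits == "ledger" else (visits_high, visits_low)
    )
    usual = StrategyInputs(
        drug_cost_year=lognormal(4.36, 1.39, base=206.43),
        test_cost_year=uniform(20.37, 37.83, base=29.10),
        programme_fee_year=fixed(0.0),
        n_visits_year=usual_visits,
        hazard_ratio=normal(0.6150, 0.0089, lower=0.0, upper=1.5),
    )
    programme = StrategyInputs(
        drug_cost_year=lognormal(4.59, 1.26, base=216.55),
        test_cost_year=uniform(25.33, 47.04, base=36.19),
        programme_fee_year=uniform(10.26, 19.06, base=14.66),
        n_visits_year=programme_visits,
        hazard_ratio=normal(0.5124, 0.0131, lower=0.0, upper=1.5),
        hazard_ratio_scenario=uniform(0.45, 0.57, base=0.51),
    )
    common = CommonInputs(
        visit_cost=uniform(6.74, 12.52, base=9.63),
        overhead_per_visit=uniform(1.39, 2.57, base=1.98),
        ambulance_cost_year=uniform(12.21, 22.67, base=17.44),
        drug_coverage=uniform(0.40, 1.00, base=0.70, lower=0.0, upper=1.0),
        event_hospital_cost=lognormal(8.24, 1.39, base=10041.65),
        first_year_test_cost=uniform(82.44, 153.11, base=117.78),
        risk_int_65_74=uniform(0.0223, 0.0285, base=0.0255),
        risk_int_75plus=uniform(0.0300, 0.0500, base=0.0400),
        risk_high_65_74=uniform(0.0300, 0.0350, base=0.0325),
        risk_high_75plus=uniform(0.1500, 0.2500, base=0.2000),
        p_sudden_death=uniform(0.0600, 0.1400, base=0.1000),
        p_unrecognized=uniform(0.2500, 0.4000, base=0.3670),
        cfr_assisted_65_74=uniform(0.1000, 0.2000, base=0.1500),
        cfr_assisted_75plus=uniform(0.2500, 0.3500, base=0.3000),
        cfr_unassisted_65_74=uniform(0.2000, 0.4000, base=0.3000),
        cfr_unassisted_75plus=uniform(0.5500, 0.6500, base=0.6000),
        p_start_intermediate=uniform(0.0, 1.0, base=0.70),
        start_age=uniform(65.0, 80.0, base=65.0, integer=True),
    )
    return ParameterSet(usual=usual, programme=programme, common=common,
                        econ=econ or EconSettings())


# ---------------------------------------------------------------------------
# File round-trip (YAML, schema version 1)
# ---------------------------------------------------------------------------

_SPEC_KEYS = ("kind", "base", "p1", "p2", "lower", "upper", "integer")


def _spec_to_dict(spec: DistributionSpec) -> dict:
    d = {"kind": spec.kind, "base": spec.base}
    if spec.kind != "fixed":
        d["p1"] = spec.p1
        d["p2"] = spec.p2
    if spec.lower is not None:
        d["lower"] = spec.lower
    if spec.upper is not None:
        d["upper"] = spec.upper
    if spec.integer:
        d["integer"] = True
    return d


def _spec_from_dict(d: dict, name: str) -> DistributionSpec:
    if not isinstance(d, dict) or "kind" not in d or "base" not in d:
        raise SchemaError(f"parameter {name!r} must be a mapping with 'kind' and 'base'")
    unknown = set(d) - set(_SPEC_KEYS)
    if unknown:
        raise SchemaError(f"parameter {name!r}: unknown keys {sorted(unknown)}")
    try:
        return DistributionSpec(
            kind=d["kind"], base=float(d["base"]),
            p1=float(d.get("p1", 0.0)), p2=float(d.get("p2", 0.0)),
            lower=d.get("lower"), upper=d.get("upper"),
            integer=bool(d.get("integer", False)),
        )
    except ValidationError:
        raise
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"parameter {name!r}: {exc}") from exc


def _block_to_dict(obj) -> dict:
    out = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, DistributionSpec):
            out[f.name] = _spec_to_dict(v)
        elif v is None:
            continue
        elif isinstance(v, tuple):
            out[f.name] = list(v)
        else:
            out[f.name] = v
    return out


def _block_from_dict(cls, d: dict, block: str):
    if not isinstance(d, dict):
        raise SchemaError(f"block {block!r} must be a mapping")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in d:
            val = d[f.name]
            if isinstance(val, dict):
                kwargs[f.name] = _spec_from_dict(val, f"{block}.{f.name}")
            elif isinstance(val, list):
                kwargs[f.name] = tuple(val)
            else:
                kwargs[f.name] = val
        elif f.default is dataclasses.MISSING and f.default_factory is dataclasses.MISSING:
            raise SchemaError(f"missing required key {block}.{f.name}")
    unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
    if unknown:
        raise SchemaError(f"block {block!r}: unknown keys {sorted(unknown)}")
    return cls(**kwargs)


def save_parameters(ps: ParameterSet, path: Union[str, Path]) -> None:
    """Write a ParameterSet to a YAML file (schema version 1)."""
    doc = {
        "schema": SCHEMA_VERSION,
        "usual": _block_to_dict(ps.usual),
        "programme": _block_to_dict(ps.programme),
        "common": _block_to_dict(ps.common),
        "econ": _block_to_dict(ps.econ),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_parameters(path: Union[str, Path]) -> ParameterSet:
    """Read a ParameterSet from YAML; raises SchemaError / ValidationError."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise SchemaError("parameter file must contain a mapping")
    if doc.get("schema") != SCHEMA_VERSION:
        raise SchemaError(f"unsupported or missing schema version {doc.get('schema')!r}")
    for key in ("usual", "programme", "common"):
        if key not in doc:
            raise SchemaError(f"missing required key {key!r}")
    return ParameterSet(
        usual=_block_from_dict(StrategyInputs, doc["usual"], "usual"),
        programme=_block_from_dict(StrategyInputs, doc["programme"], "programme"),
        common=_block_from_dict(CommonInputs, doc["common"], "common"),
        econ=_block_from_dict(EconSettings, doc.get("econ", {}), "econ"),
    )


# ---------------------------------------------------------------------------
# Internal-consistency report
# ---------------------------------------------------------------------------

def validate_distributions(ps: ParameterSet, flag_threshold: float = 0.05) -> pd.DataFrame:
    """Check each base case against its distribution's implied centre.

    For uniform laws the implied centre is the interval midpoint; for
    lognormal laws it is exp(mu + sigma^2/2).  Relative deviations above
    ``flag_threshold`` are flagged.  Three inputs carry deliberately
    off-centre uniform bands (the base is an empirical point estimate and
    the interval a scenario range): the unrecognised-event probability,
    the starting proportion at intermediate risk, and the starting age.
    The report surfaces them; it never raises.
    """
    rows = []
    for block in ("usual", "programme", "common"):
        obj = getattr(ps, block)
        for f in dataclasses.fields(obj):
            spec = getattr(obj, f.name)
            if not isinstance(spec, DistributionSpec):
                continue
            name = f"{block}.{f.name}"
            if spec.kind == "uniform":
                implied = 0.5 * (spec.p1 + spec.p2)
                dev = abs(spec.base - implied) / max(1.0, abs(spec.base))
            elif spec.kind == "lognormal":
                implied = spec.mean()
                dev = abs(spec.base - implied) / abs(spec.base)
            else:
                implied, dev = spec.base, 0.0
            rows.append({
                "parameter": name, "kind": spec.kind, "base": spec.base,
                "implied_centre": implied, "deviation": dev,
                "flagged": bool(dev > flag_threshold),
            })
    return pd.DataFrame(rows)
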