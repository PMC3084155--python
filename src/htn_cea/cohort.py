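"""Markov cohort engine for the two hypertension-treatment strategies.

States: ``intermediate_risk`` (hypertension and age as the only risk
factors), ``high_risk`` (prior cardiovascular events, diabetes, or other
factors giving a high predicted risk), ``dead_cv`` and ``dead_other``
(absorbing).  Cycles last one year.  Within each cycle a live patient
follows one of three mutually exclusive paths: an acute cardiovascular
event, death from non-cardiovascular causes, or no event.  The event
sub-tree distinguishes sudden death, unrecognised (unassisted) events
and hospital-assisted events, with case fatality depending on
assistance and age band; survivors of any event start the next cycle at
high risk.  One life-year is credited per completed cycle; the annual
treatment cost is charged to everyone alive at cycle start and the
hospital episode cost only to assisted events.  Costs and life-years
are discounted at the same annual rate, with cycle 0 undiscounted.

Three evaluation routes implement the identical tree:

* :func:`run_cohort` — deterministic cohort expectation with a full
  per-cycle trace (the reference, readable implementation),
* :func:`run_cohort_draws` — the same expectation vectorised across
  many parameter draws at once (used by the probabilistic analysis),
* :func:`run_microsim` — individual-level Monte-Carlo simulation, kept
  as a brute-force oracle for the cohort expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .costing import annual_treatment_cost
from .distributions import ValidationError
from .mortality import LifeTable
from .params import (
    AcuteEventModel,
    EconSettings,
    EventRiskTable,
    ParameterSet,
    StrategyCostComponents,
    acute_event_model,
    event_risk_table,
    strategy_cost_components,
)

__all__ = [
    "HealthState",
    "CohortState",
    "CohortResult",
    "event_probability",
    "acute_event_outcome",
    "cycle_transition",
    "run_cohort",
    "run_cohort_draws",
    "run_microsim",
    "discount",
]

STATES = ("intermediate_risk", "high_risk", "dead_cv", "dead_other")
HealthState = STATES  # exported alias for the state labels

_EPS_ALIVE = 1e-9


def discount(value, rate: float, t: int):
    """Present value of a reward accrued in cycle ``t`` (cycle 0 undiscounted)."""
    if rate < 0 or t < 0:
        raise ValidationError("rate and cycle index must be >= 0")
    return value / (1.0 + rate) ** t


def event_probability(p_ref: float, hr: float) -> float:
    """Annual event probability under a strategy: reference risk times the
    strategy's hazard ratio, applied on the probability scale and capped at 1."""
    if not 0.0 <= p_ref <= 1.0:
        raise ValidationError(f"p_ref {p_ref} outside [0, 1]")
    if hr <= 0:
        raise ValidationError(f"hazard ratio must be > 0, got {hr}")
    return min(1.0, p_ref * hr)


def acute_event_outcome(age: float, aem: AcuteEventModel) -> dict[str, float]:
    """Outcome distribution of one acute event at the given age.

    Sudden deaths are unassisted fatal events; the unrecognised fraction
    applies to non-sudden events only.  The four probabilities sum to 1.
    """
    psd, punrec = aem.p_sudden_death, aem.p_unrecognized
    cfr_a, cfr_u = aem.cfr(True, age), aem.cfr(False, age)
    unassisted = (1.0 - psd) * punrec
    assisted = (1.0 - psd) * (1.0 - punrec)
    return {
        "unassisted_die": psd + unassisted * cfr_u,
        "unassisted_survive": unassisted * (1.0 - cfr_u),
        "assisted_die": assisted * cfr_a,
        "assisted_survive": assisted * (1.0 - cfr_a),
    }


@dataclass
class CohortState:
    """Occupancy fractions plus the cohort's current age."""

    intermediate: float
    high: float
    dead_cv: float
    dead_other: float
    age: int

    def __post_init__(self) -> None:
        occ = (self.intermediate, self.high, self.dead_cv, self.dead_other)
        if any(v < -1e-12 for v in occ):
            raise ValidationError("occupancy fractions must be >= 0")
        if abs(sum(occ) - 1.0) > 1e-9:
            raise ValidationError(f"occupancy must sum to 1, got {sum(occ)}")

    @property
    def alive(self) -> float:
        return self.intermediate + self.high


@dataclass
class CohortResult:
    """Discounted per-patient totals for one strategy, with a per-cycle trace."""

    disc_cost: float
    disc_lyg: float
    trace: Optional[pd.DataFrame] = None
    se_cost: Optional[float] = None
    se_lyg: Optional[float] = None


def _lyg_reward(alive_start: float, alive_end: float, settings: EconSettings):
    """Life-year reward for one cycle under the configured convention.

    Default: one year per completed cycle, zero in the year of death.
    The half-cycle correction and the half-year-at-death credit both
    replace that with the mid-cycle average (they coincide when death is
    the only way to leave the live states within a cycle).
    """
    if settings.half_cycle_correction or settings.credit_half_year_at_death:
        return 0.5 * (alive_start + alive_end)
    return alive_end


def cycle_transition(state: CohortState, params: ParameterSet, strategy: str,
                     lt: LifeTable, first_cycle: bool = False):
    """Advance the cohort one annual cycle.

    Returns ``(next_state, cycle_cost, cycle_lyg, event_count)``, all
    undiscounted and per initial patient.
    """
    settings = params.econ
    if state.age >= settings.max_age:
        raise ValidationError(f"cycle starting at age {state.age} >= max_age")
    costs = strategy_cost_components(params, strategy)
    risks = event_risk_table(params)
    aem = acute_event_model(params)
    hr = getattr(params, strategy).hazard_ratio.base

    alive_start = state.alive
    if alive_start <= 0.0:
        nxt = CohortState(0.0, 0.0, state.dead_cv, state.dead_other, state.age + 1)
        return nxt, 0.0, 0.0, 0.0

    qnc = float(lt.lookup(state.age))
    outcome = acute_event_outcome(state.age, aem)
    p_die_event = outcome["unassisted_die"] + outcome["assisted_die"]
    assisted_frac = (1.0 - aem.p_sudden_death) * (1.0 - aem.p_unrecognized)

    pe_int = event_probability(risks.p_ref(state.age, "intermediate"), hr)
    pe_high = event_probability(risks.p_ref(state.age, "high"), hr)

    events_int = state.intermediate * pe_int
    events_high = state.high * pe_high
    events = events_int + events_high
    cv_deaths = events * p_die_event
    event_survivors = events - cv_deaths

    stay_int = state.intermediate * (1.0 - pe_int)
    stay_high = state.high * (1.0 - pe_high)
    other_deaths = (stay_int + stay_high) * qnc

    nxt = CohortState(
        intermediate=stay_int * (1.0 - qnc),
        high=stay_high * (1.0 - qnc) + event_survivors,
        dead_cv=state.dead_cv + cv_deaths,
        dead_other=state.dead_other + other_deaths,
        age=state.age + 1,
    )
    cost = alive_start * annual_treatment_cost(costs, first_cycle=first_cycle)
    cost += events * assisted_frac * costs.event_hospital_cost
    lyg = _lyg_reward(alive_start, nxt.alive, settings)
    return nxt, cost, lyg, events


def run_cohort(params: ParameterSet, strategy: str, settings: Optional[EconSettings] = None,
               lt: Optional[LifeTable] = None, keep_trace: bool = True) -> CohortResult:
    """Lifetime deterministic cohort run for one strategy.

    The cohort enters at the configured starting age, split between the
    intermediate- and high-risk strata, and is propagated annually until
    the terminal age or extinction.  Rewards of cycle ``t`` are
    discounted by ``(1+r)**-t``.
    """
    if settings is not None:
        import dataclasses as _dc
        params = _dc.replace(params, econ=settings)
    settings = params.econ
    if lt is None:
        from .mortality import synthetic_life_table
        lt = synthetic_life_table(max_age=settings.max_age)
    start_age = int(params.common.start_age.base)
    p_int = params.common.p_start_intermediate.base
    if not (65 <= start_age < settings.max_age):
        raise ValidationError(f"start_age {start_age} outside [65, max_age)")

    state = CohortState(p_int, 1.0 - p_int, 0.0, 0.0, start_age)
    r = settings.discount_rate
    disc_cost = disc_lyg = 0.0
    rows = []
    for t in range(settings.max_age - start_age):
        prev = state
        state, cost, lyg, events = cycle_transition(
            prev, params, strategy, lt, first_cycle=(t == 0))
        df = 1.0 / (1.0 + r) ** t
        disc_cost += cost * df
        disc_lyg += lyg * df
        if keep_trace:
            rows.append({
                "cycle": t, "age": prev.age,
                "intermediate": prev.intermediate, "high": prev.high,
                "dead_cv": prev.dead_cv, "dead_other": prev.dead_other,
                "events": events,
                "cv_deaths": state.dead_cv - prev.dead_cv,
                "other_deaths": state.dead_other - prev.dead_other,
                "cost": cost, "lyg": lyg,
                "disc_cost": cost * df, "disc_lyg": lyg * df,
            })
        if state.alive < _EPS_ALIVE:
            break
    trace = pd.DataFrame(rows) if keep_trace else None
    return CohortResult(disc_cost=disc_cost, disc_lyg=disc_lyg, trace=trace)


# ---------------------------------------------------------------------------
# Vectorised evaluation across parameter draws
# ---------------------------------------------------------------------------

def run_cohort_draws(draws: dict, strategy: str, discount_rate: float,
                     lt: LifeTable, settings: EconSettings):
    """Cohort expectation evaluated simultaneously for many parameter draws.

    ``draws`` maps dotted parameter names (``common.drug_coverage``,
    ``usual.hazard_ratio`` ...) to equal-length arrays; see
    :func:`htn_cea.psa.draw_inputs`.  Returns ``(disc_cost, disc_lyg)``
    arrays.  Implements exactly the tree of :func:`cycle_transition`.
    """
    c = lambda k: np.asarray(draws[f"common.{k}"], dtype=float)
    s = lambda k: np.asarray(draws[f"{strategy}.{k}"], dtype=float)

    coverage = c("drug_coverage") if settings.apply_drug_coverage else 1.0
    treat = (s("drug_cost_year") * coverage + s("test_cost_year")
             + s("programme_fee_year")
             + s("n_visits_year") * (c("visit_cost") + c("overhead_per_visit"))
             + c("ambulance_cost_year"))
    first_year_extra = c("first_year_test_cost")
    hosp = c("event_hospital_cost")
    hr = s("hazard_ratio")

    psd, punrec = c("p_sudden_death"), c("p_unrecognized")
    assisted_frac = (1.0 - psd) * (1.0 - punrec)
    p_die_young = psd + (1.0 - psd) * (punrec * c("cfr_unassisted_65_74")
                                       + (1.0 - punrec) * c("cfr_assisted_65_74"))
    p_die_old = psd + (1.0 - psd) * (punrec * c("cfr_unassisted_75plus")
                                     + (1.0 - punrec) * c("cfr_assisted_75plus"))

    start_age = c("start_age").astype(int)
    p_int0 = c("p_start_intermediate")
    n = start_age.shape[0]

    I = p_int0.copy()
    H = 1.0 - p_int0
    disc_cost = np.zeros(n)
    disc_lyg = np.zeros(n)
    mid_cycle = settings.half_cycle_correction or settings.credit_half_year_at_death

    horizon = int(settings.max_age - start_age.min())
    for t in range(horizon):
        age = start_age + t
        active = age < settings.max_age
        alive_start = I + H
        if not (active & (alive_start > _EPS_ALIVE)).any():
            break
        old = age >= 75
        p_ref_int = np.where(old, c("risk_int_75plus"), c("risk_int_65_74"))
        p_ref_high = np.where(old, c("risk_high_75plus"), c("risk_high_65_74"))
        pe_int = np.minimum(1.0, p_ref_int * hr)
        pe_high = np.minimum(1.0, p_ref_high * hr)
        p_die = np.where(old, p_die_old, p_die_young)
        qnc = lt.lookup(np.minimum(age, settings.max_age))

        events = I * pe_int + H * pe_high
        event_survivors = events * (1.0 - p_die)
        stay_int = I * (1.0 - pe_int)
        stay_high = H * (1.0 - pe_high)

        new_I = stay_int * (1.0 - qnc)
        new_H = stay_high * (1.0 - qnc) + event_survivors

        tc = treat + (first_year_extra if t == 0 else 0.0)
        cost = alive_start * tc + events * assisted_frac * hosp
        alive_end = new_I + new_H
        lyg = 0.5 * (alive_start + alive_end) if mid_cycle else alive_end

        df = 1.0 / (1.0 + discount_rate) ** t
        disc_cost += np.where(active, cost, 0.0) * df
        disc_lyg += np.where(active, lyg, 0.0) * df
        I = np.where(active, new_I, I)
        H = np.where(active, new_H, H)
    return disc_cost, disc_lyg


# ---------------------------------------------------------------------------
# Microsimulation oracle
# ---------------------------------------------------------------------------

def run_microsim(params: ParameterSet, strategy: str, settings: Optional[EconSettings] = None,
                 lt: Optional[LifeTable] = None, n_individuals: int = 100_000,
                 seed: Optional[int] = None) -> CohortResult:
    """Individual-level Monte-Carlo simulation of the identical event tree.

    Each of ``n_individuals`` patients walks independently through the
    yearly event / assistance / death tree.  Returns the mean discounted
    cost and life-years with their Monte-Carlo standard errors — the
    brute-force check on :func:`run_cohort`.
    """
    if n_individuals < 1:
        raise ValidationError("n_individuals must be >= 1")
    if settings is not None:
        import dataclasses as _dc
        params = _dc.replace(params, econ=settings)
    settings = params.econ
    if lt is None:
        from .mortality import synthetic_life_table
        lt = synthetic_life_table(max_age=settings.max_age)
    rng = np.random.default_rng(seed)

    costs = strategy_cost_components(params, strategy)
    risks = event_risk_table(params)
    aem = acute_event_model(params)
    hr = getattr(params, strategy).hazard_ratio.base
    start_age = int(params.common.start_age.base)
    p_int = params.common.p_start_intermediate.base
    r = settings.discount_rate
    treat = annual_treatment_cost(costs, first_cycle=False)
    first_extra = costs.first_year_test_cost
    mid_cycle = settings.half_cycle_correction or settings.credit_half_year_at_death

    n = n_individuals
    # state codes: 0 intermediate, 1 high, 2 dead_cv, 3 dead_other
    state = np.where(rng.random(n) < p_int, 0, 1).astype(np.int8)
    tot_cost = np.zeros(n)
    tot_lyg = np.zeros(n)

    for t in range(settings.max_age - start_age):
        age = start_age + t
        alive = state < 2
        if not alive.any():
            break
        df = 1.0 / (1.0 + r) ** t
        pe = np.where(state == 0, event_probability(risks.p_ref(age, "intermediate"), hr),
                      event_probability(risks.p_ref(age, "high"), hr))
        out = acute_event_outcome(age, aem)
        qnc = float(lt.lookup(age))

        tc = treat + (first_extra if t == 0 else 0.0)
        tot_cost[alive] += tc * df

        u = rng.random(n)
        event = alive & (u < pe)
        # resolve the event sub-tree
        v = rng.random(n)
        p_ua_die = out["unassisted_die"]
        p_ua = p_ua_die + out["unassisted_survive"]
        p_a_die_cum = p_ua + out["assisted_die"]
        ev_die = event & ((v < p_ua_die) | ((v >= p_ua) & (v < p_a_die_cum)))
        assisted = event & (v >= p_ua)
        tot_cost[assisted] += costs.event_hospital_cost * df
        # non-event branch: background mortality
        w = rng.random(n)
        other_death = alive & ~event & (w < qnc)

        ev_survive = event & ~ev_die
        was_alive = alive.copy()
        state[ev_die] = 2
        state[other_death] = 3
        state[ev_survive] = 1
        alive_end = state < 2
        if mid_cycle:
            tot_lyg[was_alive] += 0.5 * df
            tot_lyg[alive_end] += 0.5 * df
        else:
            tot_lyg[alive_end] += df

    return CohortResult(
        disc_cost=float(tot_cost.mean()),
        disc_lyg=float(tot_lyg.mean()),
        se_cost=float(tot_cost.std(ddof=1) / np.sqrt(n)) if n > 1 else None,
        se_lyg=float(tot_lyg.std(ddof=1) / np.sqrt(n)) if n > 1 else None,
    )
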