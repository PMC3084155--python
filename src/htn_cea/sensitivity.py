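"""One-way sensitivity, tornado ranking, discount-rate scenarios, scaling.

One-way sweeps hold every input at its base case and move one parameter
between its distribution bounds (uniform endpoints; 2.5/97.5 percentiles
for normal and lognormal laws).  The tornado ranks parameters by the
spread they induce in the incremental net monetary benefit at the
willingness-to-pay threshold — NMB is used as the uniform ranking metric
because the ICER is unstable and changes meaning near zero incremental
effect; per-bound ICERs are reported alongside where defined.  The
discount rate is a structural variable: it is swept over the scenario
set rather than sampled, and the scenario analysis re-evaluates the same
parameter draws at every rate (common random numbers).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import dataclasses as _dc
import numpy as np
import pandas as pd

from .cohort import run_cohort
from .distributions import ValidationError
from .mortality import LifeTable, synthetic_life_table
from .params import EconSettings, ParameterSet
from .psa import (
    ICER,
    PSAResult,
    ceac,
    classification_fractions,
    draw_inputs,
    evaluate_draws,
    icer,
    probability_cost_effective,
)

__all__ = [
    "TornadoEntry",
    "deterministic_increments",
    "one_way",
    "tornado",
    "discount_scenarios",
    "population_impact",
]


@dataclass(frozen=True)
class TornadoEntry:
    """One-way sweep result for a single parameter."""

    parameter: str
    low_input: float
    high_input: float
    nmb_low: float     # incremental NMB at the lower input bound
    nmb_high: float    # incremental NMB at the upper input bound
    icer_low: ICER
    icer_high: ICER

    @property
    def spread(self) -> float:
        return abs(self.nmb_high - self.nmb_low)


def deterministic_increments(params: ParameterSet, lt: LifeTable,
                             settings: Optional[EconSettings] = None):
    """Paired deterministic cohort runs; returns (delta_cost, delta_effect)."""
    if settings is not None:
        params = _dc.replace(params, econ=settings)
    usual = run_cohort(params, "usual", lt=lt, keep_trace=False)
    prog = run_cohort(params, "programme", lt=lt, keep_trace=False)
    return prog.disc_cost - usual.disc_cost, prog.disc_lyg - usual.disc_lyg


def _evaluate_at(params: ParameterSet, name: str, value: float, lt: LifeTable):
    ps = params.replace_spec(name, params.get_spec(name).with_base(value))
    dc, de = deterministic_increments(ps, lt)
    return dc, de


def one_way(base: ParameterSet, param_name: str, low: float, high: float,
            settings: Optional[EconSettings] = None,
            lt: Optional[LifeTable] = None) -> TornadoEntry:
    """Deterministic sweep of one parameter between two bounds."""
    if low > high:
        raise ValidationError(f"low {low} > high {high}")
    if settings is not None:
        base = _dc.replace(base, econ=settings)
    lt = lt if lt is not None else synthetic_life_table(max_age=base.econ.max_age)
    wtp = base.econ.wtp_threshold
    base.get_spec(param_name)  # raises KeyError for unknown parameters
    dc_lo, de_lo = _evaluate_at(base, param_name, low, lt)
    dc_hi, de_hi = _evaluate_at(base, param_name, high, lt)
    return TornadoEntry(
        parameter=param_name, low_input=low, high_input=high,
        nmb_low=wtp * de_lo - dc_lo, nmb_high=wtp * de_hi - dc_hi,
        icer_low=icer(dc_lo, de_lo), icer_high=icer(dc_hi, de_hi),
    )


def tornado(base: ParameterSet, settings: Optional[EconSettings] = None,
            lt: Optional[LifeTable] = None,
            include_discount: bool = True) -> list[TornadoEntry]:
    """One-way sweeps of every sampled parameter, ranked by NMB spread.

    The discount rate is included as a structural entry swept over the
    scenario rate set; its NMB low/high are the extremes over that set.
    """
    if settings is not None:
        base = _dc.replace(base, econ=settings)
    settings = base.econ
    lt = lt if lt is not None else synthetic_life_table(max_age=settings.max_age)
    entries = []
    for name in base.sampled_names():
        bounds = base.get_spec(name).bounds()
        if bounds is None:
            continue
        entries.append(one_way(base, name, bounds[0], bounds[1], lt=lt))
    # structural discount-rate sweep
    wtp = settings.wtp_threshold
    rates = sorted(settings.scenario_rates)
    if include_discount and rates:
        nmbs = []
        for rate in rates:
            dc, de = deterministic_increments(
                base, lt, settings=_dc.replace(settings, discount_rate=rate))
            nmbs.append((rate, wtp * de - dc, icer(dc, de)))
        lo = min(nmbs, key=lambda x: x[1])
        hi = max(nmbs, key=lambda x: x[1])
        entries.append(TornadoEntry(
            parameter="econ.discount_rate",
            low_input=lo[0], high_input=hi[0],
            nmb_low=lo[1], nmb_high=hi[1], icer_low=lo[2], icer_high=hi[2],
        ))
    entries.sort(key=lambda e: e.spread, reverse=True)
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([
        {"parameter": e.parameter, "low_input": e.low_input,
         "high_input": e.high_input, "nmb_low": e.nmb_low,
         "nmb_high": e.nmb_high, "spread": e.spread}
        for e in entries
    ])


def discount_scenarios(base: ParameterSet, rates: Optional[Sequence[float]] = None,
                       settings: Optional[EconSettings] = None,
                       lt: Optional[LifeTable] = None,
                       n_iterations: Optional[int] = None,
                       seed: Optional[int] = None) -> dict[float, dict]:
    """Base-case and probabilistic results at each structural discount rate.

    A single set of parameter draws is evaluated at every rate, so
    differences between rates reflect discounting only.  Per rate the
    summary holds the deterministic ICER, the dominance and
    cost-effectiveness fractions at the configured threshold, and the
    acceptability curve.
    """
    if settings is not None:
        base = _dc.replace(base, econ=settings)
    settings = base.econ
    rates = tuple(rates) if rates is not None else settings.scenario_rates
    if any(r < 0 or r > 0.2 for r in rates):
        raise ValidationError("scenario rates must lie in [0, 0.2]")
    lt = lt if lt is not None else synthetic_life_table(max_age=settings.max_age)
    n = n_iterations if n_iterations is not None else settings.psa_iterations
    seed = seed if seed is not None else settings.seed
    rng = np.random.default_rng(seed)
    draws = draw_inputs(base, rng, n)

    out = {}
    for rate in rates:
        s_rate = _dc.replace(settings, discount_rate=rate)
        dc, de = deterministic_increments(base, lt, settings=s_rate)
        res = evaluate_draws(draws, rate, lt, settings, seed=seed)
        det_icer = icer(dc, de)
        out[rate] = {
            "deterministic_delta_cost": dc,
            "deterministic_delta_effect": de,
            "deterministic_icer": det_icer.value if det_icer.kind == "ratio" else det_icer.kind,
            "fractions": classification_fractions(res, settings.wtp_threshold),
            "p_cost_effective": probability_cost_effective(res, settings.wtp_threshold),
            "ceac": ceac(res, settings.wtp_grid),
            "psa": res,
        }
    return out


def population_impact(delta_effect_per_patient: float, population_size: float) -> float:
    """Total life-years gained when the programme covers a whole population."""
    if population_size < 0:
        raise ValidationError("population_size must be >= 0")
    return delta_effect_per_patient * population_size
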