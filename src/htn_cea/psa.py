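"""Probabilistic sensitivity analysis.

Every non-fixed model input is redrawn from its distribution in each
iteration; the discount rate is structural and never sampled.  Inputs in
the common block (unit costs, reference risks, acute-event pathway,
cohort composition, starting age) are drawn once per iteration and
shared by both strategies, so each iteration is a paired comparison;
strategy-specific inputs (drug/test costs, programme fee, visit counts,
hazard ratios) are drawn independently per strategy.  Each draw is
evaluated as a full cohort expectation (not a single simulated patient),
and the incremental cost and effectiveness pairs feed the ICER summary,
the dominance classification, and the acceptability curves.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cohort import run_cohort_draws
from .distributions import DistributionSpec, ValidationError
from .mortality import LifeTable, synthetic_life_table
from .params import EconSettings, ParameterSet

__all__ = [
    "PSAResult",
    "draw_inputs",
    "sample_parameter_set",
    "run_psa",
    "evaluate_draws",
    "icer",
    "ICER",
    "classify_iteration",
    "classification_fractions",
    "ceac",
    "summarize_psa",
]

STRATEGIES = ("usual", "programme")

#: cohort-composition inputs held at base by the PSA unless
#: ``EconSettings.sample_cohort_composition`` is set; they are swept by the
#: tornado instead (see :mod:`htn_cea.sensitivity`).
STRUCTURAL_PARAMS = ("common.p_start_intermediate", "common.start_age")


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def draw_inputs(base: ParameterSet, rng: np.random.Generator, n: int,
                hr_scenario: bool = False) -> dict[str, np.ndarray]:
    """Draw ``n`` parameter sets as a dict of dotted-name -> array.

    Draw order is canonical (common block, then usual, then programme,
    field order as declared), so results are reproducible for a given
    generator state.  Fixed parameters are emitted as constant arrays, as
    are the structural cohort-composition inputs (starting age, starting
    stratum mix) unless ``sample_cohort_composition`` is enabled in the
    economic settings.  With ``hr_scenario`` the programme hazard ratio
    is drawn from its uniform scenario band instead of its normal law
    (never both).
    """
    sample_composition = base.econ.sample_cohort_composition
    out: dict[str, np.ndarray] = {}
    for block in ("common", "usual", "programme"):
        obj = getattr(base, block)
        for f in dataclasses.fields(obj):
            spec = getattr(obj, f.name)
            if not isinstance(spec, DistributionSpec):
                continue
            if f.name == "hazard_ratio_scenario":
                continue
            name = f"{block}.{f.name}"
            if (hr_scenario and block == "programme" and f.name == "hazard_ratio"
                    and obj.hazard_ratio_scenario is not None):
                spec = obj.hazard_ratio_scenario
            if name in STRUCTURAL_PARAMS and not sample_composition:
                out[name] = np.full(n, spec.base, dtype=float)
                continue
            out[name] = spec.sample(rng, n)
    return out


def sample_parameter_set(base: ParameterSet, rng: np.random.Generator,
                         hr_scenario: bool = False) -> ParameterSet:
    """One random parameter set, returned with every law collapsed to the
    drawn value (fixed specs); an all-fixed input is returned unchanged."""
    if not any(not base.get_spec(n).is_fixed for n in base.sampled_names()):
        return base
    draws = draw_inputs(base, rng, 1, hr_scenario=hr_scenario)
    ps = base
    for name, arr in draws.items():
        ps = ps.replace_spec(name, ps.get_spec(name).with_base(float(arr[0])))
    return ps


# ---------------------------------------------------------------------------
# Running
# ---------------------------------------------------------------------------

@dataclass
class PSAResult:
    """Per-iteration paired outcomes of a probabilistic analysis."""

    cost_usual: np.ndarray
    effect_usual: np.ndarray
    cost_programme: np.ndarray
    effect_programme: np.ndarray
    discount_rate: float
    seed: Optional[int] = None

    @property
    def n(self) -> int:
        return self.cost_usual.shape[0]

    @property
    def delta_cost(self) -> np.ndarray:
        return self.cost_programme - self.cost_usual

    @property
    def delta_effect(self) -> np.ndarray:
        return self.effect_programme - self.effect_usual

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cost_usual": self.cost_usual, "effect_usual": self.effect_usual,
            "cost_programme": self.cost_programme,
            "effect_programme": self.effect_programme,
            "delta_cost": self.delta_cost, "delta_effect": self.delta_effect,
        })


def evaluate_draws(draws: dict, discount_rate: float, lt: LifeTable,
                   settings: EconSettings, seed: Optional[int] = None) -> PSAResult:
    """Evaluate pre-drawn parameter arrays at one discount rate.

    Reusing the same draws across rates implements common random numbers
    for the structural discount-rate scenarios.
    """
    cu, eu = run_cohort_draws(draws, "usual", discount_rate, lt, settings)
    cp, ep = run_cohort_draws(draws, "programme", discount_rate, lt, settings)
    return PSAResult(cost_usual=cu, effect_usual=eu, cost_programme=cp,
                     effect_programme=ep, discount_rate=discount_rate, seed=seed)


def run_psa(base: ParameterSet, settings: Optional[EconSettings] = None,
            lt: Optional[LifeTable] = None, n_iterations: Optional[int] = None,
            seed: Optional[int] = None, hr_scenario: bool = False) -> PSAResult:
    """Full probabilistic sensitivity analysis at the configured discount rate."""
    settings = settings or base.econ
    lt = lt if lt is not None else synthetic_life_table(max_age=settings.max_age)
    n = n_iterations if n_iterations is not None else settings.psa_iterations
    if n < 1:
        raise ValidationError("n_iterations must be >= 1")
    seed = seed if seed is not None else settings.seed
    rng = np.random.default_rng(seed)
    draws = draw_inputs(base, rng, n, hr_scenario=hr_scenario)
    return evaluate_draws(draws, settings.discount_rate, lt, settings, seed=seed)


# ---------------------------------------------------------------------------
# ICER, dominance, CEAC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ICER:
    """Incremental cost-effectiveness ratio or its dominance classification."""

    kind: str  # "ratio" | "dominant" | "dominated" | "undefined"
    value: Optional[float] = None


def icer(delta_cost: float, delta_effect: float) -> ICER:
    """Classify an incremental (cost, effect) pair.

    ``dominant``: more effective and less costly; ``dominated``: less
    effective and more costly; ``undefined``: zero incremental effect.
    Otherwise the ratio delta_cost / delta_effect (a south-west pair —
    less costly, less effective — also yields a ratio).
    """
    if delta_effect == 0:
        return ICER("undefined")
    if delta_cost < 0 and delta_effect > 0:
        return ICER("dominant")
    if delta_cost > 0 and delta_effect < 0:
        return ICER("dominated")
    return ICER("ratio", delta_cost / delta_effect)


def classify_iteration(delta_cost: float, delta_effect: float, wtp: float) -> str:
    """Decision class of one iteration at a willingness-to-pay threshold.

    ``dominant`` (cheaper, more effective), ``dominated`` (costlier, less
    effective), otherwise ``cost_effective`` when the incremental net
    monetary benefit wtp*dE - dC is positive, else ``above_threshold``.
    """
    if wtp < 0:
        raise ValidationError("wtp must be >= 0")
    if delta_cost < 0 and delta_effect > 0:
        return "dominant"
    if delta_cost > 0 and delta_effect < 0:
        return "dominated"
    return "cost_effective" if wtp * delta_effect - delta_cost > 0 else "above_threshold"


def classification_fractions(res: PSAResult, wtp: float) -> dict[str, float]:
    """Fractions of iterations in each decision class (they sum to 1)."""
    dc, de = res.delta_cost, res.delta_effect
    dominant = (dc < 0) & (de > 0)
    dominated = (dc > 0) & (de < 0)
    rest = ~dominant & ~dominated
    nmb_pos = wtp * de - dc > 0
    return {
        "dominant": float(dominant.mean()),
        "cost_effective": float((rest & nmb_pos).mean()),
        "above_threshold": float((rest & ~nmb_pos).mean()),
        "dominated": float(dominated.mean()),
    }


def ceac(res: PSAResult, wtp_grid: Optional[Sequence[float]] = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves for both strategies.

    At each willingness-to-pay value, a strategy's probability of being
    the optimal choice is the fraction of iterations in which it has the
    higher net monetary benefit (ties split evenly).  The two columns
    sum to 1 row-wise.
    """
    if res.n == 0:
        raise ValidationError("empty PSA result")
    grid = np.asarray(list(wtp_grid) if wtp_grid is not None else
                      EconSettings().wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("empty WTP grid")
    # programme optimal iff wtp*dE - dC > 0
    nmb = grid[:, None] * res.delta_effect[None, :] - res.delta_cost[None, :]
    p_prog = (nmb > 0).mean(axis=1) + 0.5 * (nmb == 0).mean(axis=1)
    return pd.DataFrame({"wtp": grid, "p_programme": p_prog, "p_usual": 1.0 - p_prog})


def probability_cost_effective(res: PSAResult, wtp: float) -> float:
    """CEAC value at one threshold: P(programme has higher net benefit)."""
    return float(ceac(res, [wtp])["p_programme"].iloc[0])


def summarize_psa(res: PSAResult, wtp_threshold: float = 45_000.0) -> dict:
    """Means, 95% percentile intervals and decision fractions of a PSA."""
    if res.n < 2:
        raise ValidationError("need at least 2 iterations to summarise")

    def stats(x: np.ndarray) -> dict:
        lo, hi = np.percentile(x, [2.5, 97.5])
        return {"mean": float(x.mean()), "ci95": (float(lo), float(hi))}

    dc, de = res.delta_cost, res.delta_effect
    mean_icer = icer(float(dc.mean()), float(de.mean()))
    out = {
        "n": res.n,
        "discount_rate": res.discount_rate,
        "seed": res.seed,
        "cost_usual": stats(res.cost_usual),
        "cost_programme": stats(res.cost_programme),
        "effect_usual": stats(res.effect_usual),
        "effect_programme": stats(res.effect_programme),
        "delta_cost": stats(dc),
        "delta_effect": stats(de),
        "icer_of_means": mean_icer.value if mean_icer.kind == "ratio" else mean_icer.kind,
        "p_negative_effect": float((de < 0).mean()),
        "p_cost_effective_at_threshold": probability_cost_effective(res, wtp_threshold),
    }
    out.update(classification_fractions(res, wtp_threshold))
    return out
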