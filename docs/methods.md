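# Methods

This note documents the model implemented by `htn_cea`, its
assumptions, numerical conventions, and the design choices made where
the published description left the design open.

## Model structure

The model is a deterministic Markov cohort model with four states —
intermediate risk, high risk, cardiovascular death, other-cause death —
and 1-year cycles from the starting age (default 65) to a terminal age
(default 100). Within a cycle the live states face three mutually
exclusive paths, resolved as a tree in this order:

1. **Acute cardiovascular event**, with probability
   `min(1, p_ref(band, stratum) × HR_strategy)`. The hazard ratio is
   applied multiplicatively on the annual probability scale; at these
   magnitudes (p ≤ 0.2, HR ≈ 0.5–0.6) the difference from a rate-scale
   transformation is below 0.1%. Age bands are 65–74 and 75+, selected
   by age at cycle start.
2. **Non-cardiovascular death** with the life-table probability
   `q_noncv(age)`, applied only to the no-event branch (the event
   branch's mortality is governed by its own case fatality).
3. **No event**: remain in the current stratum.

The acute-event sub-tree: a fraction `p_sudden_death` (0.10) of events
is immediately fatal with no opportunity for care and is counted as an
unassisted death; of the remaining events, a fraction `p_unrecognized`
(0.367) receives no hospital attention. Case fatality within the year
depends on assistance and age band (assisted 0.15/0.30, unassisted
0.30/0.60 for 65–74/75+). The published description does not state how
sudden deaths and unrecognised events compose; applying the
unrecognised fraction to non-sudden events only is the reading adopted
here, making the four outcome probabilities an exact partition. Event
survivors start the next cycle at high risk regardless of origin.

**Rewards.** One life-year is credited to each patient alive at cycle
end; patients dying within the cycle earn none (no half-cycle
correction — neither is part of the published design; both are exposed
as switches in `EconSettings` and coincide numerically, since death is
the only within-cycle exit). The annual treatment cost

    drugs × coverage + tests + programme fee + visits × (fee + overhead) + ambulance

is charged to everyone alive at cycle start (care is consumed before
death); the first cycle adds a one-off diagnostic work-up (117.78
Int$). Hospital episode costs are charged to assisted events only,
fatal or not. Drug coverage (0.70) scales drug costs only — it is the
payer's share of drug spending, not of care generally. Cycle *t*
rewards are discounted by `(1+r)^−t`, cycle 0 undiscounted (standard
decision-tree convention; the discount-rate scenarios make the choice
visible). Both strategies share the acute-event pathway and hospital
cost: hospitalised patients receive the same acute care in either arm.

**Three equivalent evaluation routes** are maintained deliberately: a
readable scalar engine with a per-cycle trace; a vectorised engine
evaluating many parameter draws simultaneously (used by the PSA); and
an individual-level microsimulation that serves as a brute-force
oracle. Tests assert bitwise agreement between the first two and
3-standard-error agreement with the third on a scenario grid.

## Input conventions

Every input carries a base case and a sampling law. Lognormal laws are
parameterised by the mean and sd of the natural log — verified by the
consistency check `exp(4.36 + 1.39²/2) = 205.7 ≈ 206.43` for usual-care
drug costs; uniform laws by bounds, with symmetric intervals centred on
the base. Three uniforms are deliberately off-centre (base = point
estimate, interval = scenario band): the unrecognised-event
probability, the starting stratum mix, and the starting age; the
consistency report flags rather than rejects them. Normal hazard-ratio
draws are truncated to (0, 1.5] and probabilities to [0, 1] by
resampling — astronomically rare at the published sd values, but the
sampler must be total.

### Visit-count assignment

The two published input tables disagree about medical visits. The
per-strategy variable table prints the higher visit-count law
(lognormal(1.68, 0.89), base 7.68/yr) under usual care and the lower
one (lognormal(1.16, 0.85), base 4.72/yr) under the programme; the
costing ledger records *more* visits for the programme (8.14 vs 7.64
including specialists) and a higher per-patient annual total (361.81 vs
295.70 Int$). These cannot both be right. Read literally, the variable
table makes the programme's treatment costs *cheaper* per year, and —
combined with its avoided hospital admissions — the programme becomes
strictly dominant in the deterministic base case, contradicting the
published base-case result (usual care least costly; positive
incremental cost; ICER 1,124 Int$/LYG) and shifting every published
probabilistic fraction by 10–15 percentage points. Under the
ledger-consistent assignment (higher law to the programme) the model
reproduces the published probabilistic surface closely. The default
`base_case()` therefore uses the ledger-consistent assignment;
`base_case(visits="printed")` gives the literal reading.

### Cohort composition in the PSA

The starting age (uniform 65–80, floored to whole years) and the
starting intermediate-risk share (uniform 0–1) are treated as
*structural* inputs: swept in the tornado, held at base (65 years, 0.70)
in the PSA. Two published facts force this reading: the per-strategy
effectiveness intervals (≈ 1.1 LYG wide; sampling the starting age
widens them to ≈ 5.2 LYG), and the attribution of starting-age and
stratum-mix uncertainty to the tornado ranking rather than the Monte
Carlo scatter. `EconSettings(sample_cohort_composition=True)` restores
full sampling. The discount rate is never sampled.

Common-block inputs (unit costs, reference risks, acute-event pathway,
composition) are drawn once per iteration and shared by both
strategies — each iteration is a paired comparison; strategy blocks are
drawn independently. The uniform(0.45–0.57) programme hazard-ratio band
is a scenario mode that *replaces* the normal draw when enabled; drawing
both would double-sample one quantity. Each draw is evaluated as a full
cohort expectation (one "iteration = a set of sampled variables"), not
as a single simulated patient, which would inflate the scatter.

## Micro-costing

Ledger items are unit cost × annual quantity; capital goods are
annuitised over 5 years at 5% with the **annuity-due** factor
`AF = [(1 − (1+r)^−n)/r](1+r)` — the convention under which every
published capital row reproduces (the ordinary annuity gives 670.1, not
638.17, for the first capital item). Programme-level categories
(labour, capital, land, resources) divide by the 30,000 covered
patients (implied by 440,850.89 / 14.70 ≈ 29,990); overhead, visits and
consumption are already per patient-year. The packaged ledger stores
printed unit costs except for sub-dollar tariffs (telephone calls,
per-visit overhead, ambulance fee), which are kept at four decimals
back-derived from the printed annual totals: two-decimal rounding of a
0.12-Int$ call tariff distorts its subtotal by 1.7%. Office space is
recorded in m²-months per year. Recomputed per-item figures still
differ from print by up to ~0.1% (rounded inputs); tests assert 0.2%,
never exactness. The ledger is descriptive: the cohort model's cost
inputs come from the variable table, not the ledger.

## Synthetic background mortality

The model needs annual non-cardiovascular death probabilities for ages
65–100; the study's national life tables are not published. The
generator uses a Gompertz all-cause hazard `h(x) = a·exp(b(x−65))` with
a constant cardiovascular fraction removed multiplicatively:
`qx = (1 − e^−h)(1 − cv_fraction)`, capped at 1 at the terminal age.
Defaults `a = 0.013`, `b = 0.095` (hazard doubling time ≈ 7.3 years)
and `cv_fraction = 0.30` give a remaining all-cause life expectancy at
65 of ≈ 18.5 years, typical of the urban middle-class HMO population
modelled; the constant fraction keeps the removal transparent. The
terminal age of 100 is beyond plausible survivors: moving it to 110
changes life-years by < 0.5% (tested). The generator emulates the level
and slope of old-age mortality but not cohort trends, sex differences,
or the age profile of the cardiovascular share; consequently *absolute*
costs and life-years (and through them the base-case ICER) carry
structural uncertainty that the synthetic table cannot remove, while
increments, dominance fractions and acceptability curves — driven by
the paired hazard-ratio contrast — are insensitive to it. The table is
deliberately not calibrated to reproduce the published absolute
life-years, which would be circular.

## Sensitivity reporting

One-way sweeps move a single parameter between its distribution bounds
(uniform endpoints; 2.5/97.5 percentiles otherwise). The tornado ranks
parameters by the spread they induce in the **incremental net monetary
benefit at 45,000 Int$/LYG**: the ICER is unstable and changes meaning
near ΔE = 0, so NMB is the uniform ranking metric, with per-bound ICERs
reported alongside. The published "% of uncertainty explained"
decomposition has no stated method and is not reproduced. The discount
rate enters the tornado as a structural sweep over {0, 3, 5, 7, 12}%,
and the scenario analysis re-evaluates one shared set of draws at every
rate (common random numbers), so between-rate differences are pure
discounting.

## Problem sizes

Default analysis iterations: 100,000 (the published count). The test
suite and the acceptance script use 10,000 PSA iterations and
120,000–150,000 microsimulation individuals — sizes at which binomial
error on the reported fractions is ≈ 0.5 percentage points, an order of
magnitude below the tolerances being checked.

## Known limitations

- Events are a pooled composite (AMI, stroke, UA, TIA, HF, PAD) with a
  single cost and case-fatality set; no event-type decomposition.
- No quality-of-life weighting: effectiveness is life-years only, as in
  the source analysis.
- No treatment-adverse-event states (first-line antihypertensives show
  placebo-level side effects, and their costs would be double-counted).
- The published incremental cost (+195.3 Int$) is not recoverable from
  the published inputs under any combination rule we found; the
  deterministic ICER here (≈ 2,300 Int$/LYG) has the published sign and
  order of magnitude but not its value. Both remain far below the
  45,000 Int$/LYG threshold, so the decision conclusion is unchanged.
- Results describe an urban middle-class insured population and should
  not be extrapolated beyond it.
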