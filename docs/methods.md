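# Methods

## The model

`alloceff` implements a static, linear allocative-efficiency model for a
portfolio of health interventions. Each intervention is an independent
channel that converts annual spending into DALYs averted at a constant
rate up to a ceiling; the engine re-distributes a budget across channels
to maximize a weighted objective. The key assumptions are:

1. **Linearity.** Impact is proportional to spending below the ceiling.
   There are no diminishing returns other than the single kink at the
   ceiling, no cross-intervention synergies or overlaps, and no dynamic
   disease transmission. Only static first-order impacts are modelled;
   overlaps must be resolved in the input data.
2. **Coverage defines the ceiling.** The most that can usefully be spent
   on intervention *i* is the cost of full scale-up,
   `C_i = unit_cost_i × target_population_i × m_i`, where `m_i` is the
   allowed maximum coverage under the scenario's coverage rule.
3. **Quality reduction.** Published ICERs reflect trial or study
   conditions; delivered at national scale the effect is discounted by a
   factor `r`, giving `ce_i = (1 − r)/ICER_i` DALYs per currency unit.
   The discount applies to the *effect* (numerator), not the cost.
4. **Burden cap.** Where an intervention is linked to an attributable
   disease burden `B_i` (DALYs/year), its maximum potential impact is
   truncated: `MPI_i = min(C_i · ce_i, B_i)`. The exact construction of
   the MPI from "linear relationship between spending, cost-effectiveness
   and coverage" admits more than one algebra; the one committed here —
   the simplest consistent with those words — also tightens the
   optimizer's upper bound to `B_i / ce_i`, the spend at which the cap
   saturates, so no money is parked where it buys nothing. The cap is
   optional per intervention and can be disabled globally, which lets
   datasets without burden links run as pure spend/ICER arithmetic.

## Parameters

| parameter | units | default | why |
|---|---|---|---|
| `quality_reduction` (r) | fraction of effect | 0.30 | conventional default for scale-up attenuation; user-adjustable in `[0, 1)` |
| `max_coverage` | fraction | 0.80 | standard scale-up target used when a databook does not state one |
| coverage rule | — | unconstrained | scenario policy; `absolute_increase` (e.g. +10 points) and `tiered` (e.g. caps 90/95/100% by baseline stratum <90 / 90–94 / ≥95%) are supported |
| objective weights (w_D, w_F, w_E) | relative | (1, 0, 0) | pure health maximization; weights are normalized so only ratios matter |
| reconciliation tolerance | relative | 0.25 | mismatches between bottom-up costing and accounts data are common and resolved by judgement; the engine flags, never rescales |
| budget | currency or multiplier | required | a multiplier (e.g. 1.38) is resolved against summed current spending of in-pool interventions |

Functional-form choices that the underlying method leaves open are
isolated so alternatives are one-function changes:

- **Objective blending.** FRP and equity enter as multiplicative bonuses
  on the impact rate: `rate_i = ce_i (w_D + w_F·FRP_i + w_E·EQ_i)` with
  normalized weights (`alloceff.optimizer.score_rate`). With
  `w_F = w_E = 0` this is exactly DALYs per currency unit.
- **Coverage floors.** `allowed_max_coverage` is floored at the current
  coverage, so a rule never manufactures a ceiling below today's
  spending; disinvestment is governed by the optimizer's lower bounds
  (default 0 — full disinvestment allowed, since platform-level spending
  reductions are a legitimate model outcome).
- **Tier membership** uses half-open intervals `[lower, upper)`: a 90%
  baseline falls in the 90–94 stratum.
- **Current impact** is priced with `impact_at_spend` at current
  spending under the same `r` and caps as the optimized side, so
  current-vs-optimized comparisons are within one model.
- **Override precedence.** An observed `current_spend_override` replaces
  the bottom-up product; whether a real analysis would prefer observed
  claims over the product where both exist is a data-assembly judgement,
  so the engine adopts a fixed, documented convention.

## Optimization

The feasible set is a box plus one budget constraint and the objective
is linear, i.e. a continuous knapsack. The greedy fill — rank
non-fixed interventions by `score_rate` descending (ties by id
ascending), fund each to its effective ceiling until the budget runs
out — is the exact optimum for this class; no stochastic search is
needed and results are bit-for-bit reproducible. Fixed-spend
interventions keep their current spending; by default it is
pre-committed *inside* the budget (a config flag moves it outside the
pool). An infeasible scenario (budget below committed fixed spending)
raises with the shortfall.

Two independent verifiers guard the solver:

- `brute_force_optimize(db, config, step)`: exhaustive search over all
  allocations on a spending grid in increments of `step`, organised as
  exact dynamic programming over the grid (it visits the same solution
  set as naive enumeration but at polynomial cost). Its optimum is
  within `max_rate × step × n` of the continuous one. Guarded to ≤ 6
  non-fixed interventions and ≤ 10⁶ grid nodes.
- `lp_optimize(db, config)`: the same instance as a linear program via
  `scipy.optimize.linprog` (HiGHS).

The test suite checks greedy-vs-grid (within the grid bound) and
greedy-vs-LP (within 1e-6 relative) agreement on 100 seeded random
integer instances, plus budget monotonicity, budget conservation,
determinism, and the guarantee that the optimum dominates the current
allocation projected into the feasible box.

## Synthetic data

`generate_country` draws portfolios with the statistical shape of a
national intervention list (defaults: 135 interventions, 19 care
packages, five delivery platforms, 10% fixed lines), not the contents of
any particular country:

- unit costs and ICERs are log-normal (strictly positive, right-skewed,
  spanning orders of magnitude, as cost-effectiveness league tables do);
  defaults centre near $12/person-year and $400/DALY;
- baseline coverage is Beta(2, 2); the scale-up target is 0.8, floored
  at baseline;
- platform shares: 60% of interventions use one platform, 30% two, 10%
  three, with Dirichlet splits — so platform aggregation with fractional
  shares is exercised;
- half the interventions carry an attributable burden drawn uniformly in
  0.5–1.5× their untruncated maximum impact, so burden caps bind for
  roughly half of the linked lines;
- FRP and equity scores are Uniform(0, 1).

All draws come from one seeded `numpy` Generator; identical specs give
identical databooks. What passing tests on these portfolios *show* is
that the engine's guarantees (validity, optimality, conservation,
monotonicity) hold at realistic scale and heterogeneity. What they do
*not* show is anything about real countries: real databooks have
correlated costs and burdens, lumpy platform structures, and data gaps
that the generator does not emulate, and absolute DALY totals from
synthetic portfolios are not comparable to any published figure.

`micro_example` is a fixed five-intervention portfolio (integer
ceilings 30/40/50/60/80, strictly decreasing rates) whose optimum at
budget 100 is known from the exhaustive oracle and frozen in tests.

## Numerical choices

- Platform shares must sum to 1 within 1e-9; spending/budget
  comparisons use 1e-9 relative tolerances.
- Databook CSVs serialize floats by shortest `repr` and are parsed with
  `float_precision="round_trip"`, so write→read is the identity.
- FRP/equity scores are min-max normalized at load *only* when the
  column leaves [0, 1]; in-range columns pass through untouched
  (preserving round-trips).
- Reported percentages are rounded to integers for display only; all
  stored values are full precision, so recomputing from serialized
  results reproduces the displayed integers.
- Reconciliation defines `ratio = modelled/reported` whenever
  `reported > 0` (a program with reported spending but no modelled
  counterpart gets ratio 0 and is flagged); ratio is undefined (NaN)
  when nothing is reported.

## Problem sizes

The shipped tests and the acceptance script use portfolios of 135
interventions (50 replicates for the improvement property), 100 random
≤5-intervention instances for oracle equivalence with unit-step grids
and budgets ≤ 120, and a 10,000-draw sample for distributional sanity;
the full suite runs in a few seconds.

## Known limitations

- No dynamic disease modelling, time-phased scale-up, or
  diminishing-returns cost curves beyond the ceiling kink.
- No integer/indivisible interventions and no cross-intervention
  synergies; overlapping interventions must be pre-resolved in the data.
- ICERs enter as point estimates; no uncertainty propagation.
- No apportionment solver for splitting pooled spending lines across
  interventions; users pre-apportion into `current_spend_override`.
- The databook schema is a structural emulation of the spreadsheet
  databooks used in national applications, not byte-compatible with any
  of them.
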