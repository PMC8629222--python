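# alloceff

Allocative-efficiency analysis for health benefits package (HBP) design.

Health ministries designing or revising a benefits package face a
resource-allocation question: given a portfolio of candidate
interventions — each with a unit cost, an incremental cost-effectiveness
ratio (ICER, currency per DALY averted), a target population, current and
target coverage, and financial-risk-protection (FRP) and equity scores —
how should a fixed budget be distributed to maximize health impact?
`alloceff` answers it with a transparent, fully deterministic engine:
it reads a country *databook* of interventions, estimates current
spending and the DALYs it averts, and re-allocates the budget optimally
under coverage and policy constraints, reporting spend and impact by
delivery platform, care package and disease program. It is written for
health economists and analysts supporting priority-setting processes.

## Model

Each intervention *i* converts spending into DALYs averted linearly up
to a ceiling:

- effective cost-effectiveness: `ce_i = (1 − r) / ICER_i`, where
  `r` is a *quality reduction* factor (default 0.30) discounting
  trial-scale effect sizes to programme scale;
- investment ceiling: `C_i = u_i · P_i · m_i` with unit cost `u_i`,
  target population `P_i`, and allowed maximum coverage `m_i` given by a
  coverage rule (unconstrained, "at most +δ over baseline", or tiered
  caps by baseline stratum);
- maximum potential impact: `MPI_i = min(C_i · ce_i, B_i)` where `B_i`
  is the optional attributable disease burden;
- impact of spending `s`: `f_i(s) = min(min(s, C_i) · ce_i, MPI_i)` —
  piecewise linear, concave, saturating at the MPI.

The optimizer maximizes `Σ_i rate_i · x_i` subject to `Σ x_i ≤ B` and
`0 ≤ x_i ≤ min(C_i, B_i / ce_i)`, where
`rate_i = ce_i · (w_D + w_F · FRP_i + w_E · EQ_i)` blends DALY, FRP and
equity objectives with normalized weights. This is the continuous
knapsack problem, so the exact optimum is greedy: fund interventions in
descending order of `rate_i` until the budget is exhausted (ties broken
by id for determinism). Fixed-spend interventions keep their current
spending, by default as a pre-committed amount inside the budget. Two
independent oracles — an exhaustive search over a discrete spending grid
and a linear program (`scipy` HiGHS) — verify the optimum in the tests.

## Worked example

Generate a synthetic 135-intervention country, then optimize the current
budget and a 38%-larger envelope:

```sh
alloceff synth --n 135 --seed 1 --out data
alloceff run --databook data/synthetic-1.csv \
             --config base.json --config plus38.json --out results
```

with `base.json` = `{"budget": 1.0, "budget_is_multiplier": true,
"label": "base"}` and `plus38.json` the same with `1.38`. Output:

```
wrote data/synthetic-1.csv (135 interventions)
[base] current DALYs averted: 1,394,887  optimized: 1,742,048  gain: 25%
[plus38] current DALYs averted: 1,394,887  optimized: 1,820,027  gain: 30%
comparison tables written to results
```

Reading: at the current budget level, re-allocating spending toward the
most cost-effective interventions (within their coverage ceilings) would
avert 25% more DALYs than the current allocation; growing the envelope
by 38% raises the gain to 30%. `results/` contains the per-intervention
allocation, spend/DALY aggregates by platform, care package and program
under both allocations, and scenario comparison tables. The same is
available from Python:

```python
from alloceff import GeneratorSpec, ScenarioConfig, generate_country, run_scenario

db = generate_country(GeneratorSpec(n_interventions=135, seed=1))
res = run_scenario(db, ScenarioConfig(budget=1.0, budget_is_multiplier=True))
print(res.totals)          # current/optimized spend and DALYs
print(res.aggregates["platform"])
```

## Databook format

A CSV with one row per intervention (see
`alloceff.databook.REQUIRED_COLUMNS`) plus an optional `.meta.json`
sidecar `{name, currency_year, deflators, reported_expenditure}`.
Coverages, platform shares and scores are decimal fractions. Missing
optional columns receive documented defaults (`max_coverage` 0.8, zero
FRP/equity scores, no fixed-spend flag); FRP/equity scores supplied on a
non-[0,1] scale are min-max normalized at load. `alloceff validate
FILE` lint-checks a databook and names every violated rule.
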