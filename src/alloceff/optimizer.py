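"""Budget optimization: allocate spending across interventions to maximize
a weighted DALY / financial-risk-protection / equity objective.

Each intervention contributes to the objective linearly in its spending,
at rate ``score_rate``, up to an effective ceiling (the smaller of its
investment ceiling and the spending at which its burden cap saturates).
Maximizing a separable linear objective under a single budget constraint
and box bounds is the continuous knapsack problem, so the exact optimum
is greedy: fund interventions in descending order of score per currency
unit until the budget runs out.  Ties in the rate are broken by id so
identical inputs always produce identical allocations.

Two independent verifiers accompany the solver: an exhaustive search
over a discrete spending grid (``brute_force_optimize``) and a linear
program via :func:`scipy.optimize.linprog` (``lp_optimize``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .databook import CountryDatabook, Intervention
from .estimation import estimate_current_spend
from .impact import CoverageRule, ImpactParams, effective_ce, spend_ceiling

__all__ = [
    "ObjectiveWeights",
    "Allocation",
    "InfeasibleBudgetError",
    "score_rate",
    "effective_upper_bound",
    "optimize",
    "brute_force_optimize",
    "lp_optimize",
]

_REL_TOL = 1e-9


class InfeasibleBudgetError(ValueError):
    """Budget cannot cover the pre-committed (fixed) spending and lower bounds."""


@dataclass(frozen=True)
class ObjectiveWeights:
    """Relative importance of DALYs averted, FRP and equity.

    Weights are non-negative with at least one positive; they are
    normalized to sum to one before entering the objective, so only
    ratios matter.  ``(1, 0, 0)`` is pure health maximization.
    """

    w_dalys: float = 1.0
    w_frp: float = 0.0
    w_equity: float = 0.0

    def __post_init__(self) -> None:
        ws = (self.w_dalys, self.w_frp, self.w_equity)
        if any(w < 0 for w in ws):
            raise ValueError(f"weights must be non-negative, got {ws}")
        if not any(w > 0 for w in ws):
            raise ValueError("at least one objective weight must be positive")

    @property
    def normalized(self) -> tuple[float, float, float]:
        total = self.w_dalys + self.w_frp + self.w_equity
        return (self.w_dalys / total, self.w_frp / total, self.w_equity / total)

    @classmethod
    def from_dict(cls, d: dict) -> "ObjectiveWeights":
        return cls(
            w_dalys=d.get("w_dalys", 1.0),
            w_frp=d.get("w_frp", 0.0),
            w_equity=d.get("w_equity", 0.0),
        )

    def to_dict(self) -> dict:
        return {"w_dalys": self.w_dalys, "w_frp": self.w_frp, "w_equity": self.w_equity}


@dataclass
class Allocation:
    """A per-intervention spending plan with feasibility metadata.

    ``spend`` maps intervention id to allocated currency.  ``binding``
    maps id to ``(at_lower, at_ceiling)`` flags.  ``lower`` and
    ``ceiling`` record the box each spend was constrained to.
    """

    spend: dict[str, float]
    budget: float
    objective_value: float
    lower: dict[str, float]
    ceiling: dict[str, float]
    binding: dict[str, tuple[bool, bool]]

    @property
    def total_spend(self) -> float:
        return sum(self.spend.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": iv_id,
                "spend": s,
                "lower": self.lower[iv_id],
                "ceiling": self.ceiling[iv_id],
                "at_lower": self.binding[iv_id][0],
                "at_ceiling": self.binding[iv_id][1],
            }
            for iv_id, s in self.spend.items()
        ]
        return pd.DataFrame(rows, columns=["id", "spend", "lower", "ceiling", "at_lower", "at_ceiling"])


def score_rate(iv: Intervention, weights: ObjectiveWeights, params: ImpactParams) -> float:
    """Objective score per currency unit spent on ``iv``.

    The DALY rate (effective cost-effectiveness) scaled by the weighted
    combination of objectives: with normalized weights
    ``(w_D, w_F, w_E)`` the rate is
    ``effective_ce * (w_D + w_F * frp_score + w_E * equity_score)``.
    With all weight on DALYs this is exactly DALYs per currency unit.
    """
    w_d, w_f, w_e = weights.normalized
    return effective_ce(iv.icer, params) * (w_d + w_f * iv.frp_score + w_e * iv.equity_score)


def effective_upper_bound(iv: Intervention, rule: CoverageRule, params: ImpactParams) -> float:
    """Largest spend that still buys impact: the investment ceiling,
    tightened to the spend at which the attributable-burden cap saturates."""
    ceiling = spend_ceiling(iv, rule)
    if params.burden_cap_enabled and iv.attributable_burden is not None:
        ce = effective_ce(iv.icer, params)
        if ce > 0:
            ceiling = min(ceiling, iv.attributable_burden / ce)
    return ceiling


def _resolve_budget(db: CountryDatabook, config) -> float:
    """Absolute budget for a config whose budget may be a multiplier."""
    budget = config.budget
    if getattr(config, "budget_is_multiplier", False):
        if getattr(config, "fixed_outside_budget", False):
            pool = [iv for iv in db.interventions if not iv.fixed_spend]
        else:
            pool = list(db.interventions)
        budget = budget * sum(estimate_current_spend(iv) for iv in pool)
    if not budget >= 0:
        raise ValueError(f"budget must be >= 0, got {budget}")
    return budget


def _pool_setup(db: CountryDatabook, config):
    """Split the portfolio into the optimizable pool and pre-committed spend.

    Returns (pool, fixed, budget_for_pool, rule, params, weights, lower).
    Fixed-spend interventions keep their current spending; by default that
    amount is pre-committed *inside* the budget, a config flag moves it
    outside the pool entirely.
    """
    rule: CoverageRule = config.coverage_rule
    params: ImpactParams = config.impact_params
    weights: ObjectiveWeights = config.weights
    budget = _resolve_budget(db, config)

    fixed_ids = set(getattr(config, "fixed_ids", ()) or ())
    pool: list[Intervention] = []
    fixed: list[Intervention] = []
    for iv in db.interventions:
        (fixed if iv.fixed_spend or iv.id in fixed_ids else pool).append(iv)

    fixed_spend_total = sum(estimate_current_spend(iv) for iv in fixed)
    if getattr(config, "fixed_outside_budget", False):
        budget_for_pool = budget
    else:
        budget_for_pool = budget - fixed_spend_total
        if budget_for_pool < -_REL_TOL * max(budget, 1.0):
            raise InfeasibleBudgetError(
                f"budget {budget} cannot cover pre-committed fixed spending "
                f"{fixed_spend_total} (shortfall {fixed_spend_total - budget})"
            )
        budget_for_pool = max(budget_for_pool, 0.0)
    if not pool:
        raise InfeasibleBudgetError("no non-fixed interventions to optimize over")
    return pool, fixed, budget_for_pool, rule, params, weights


def _assemble(
    db: CountryDatabook,
    config,
    pool_spend: dict[str, float],
    pool: list[Intervention],
    fixed: list[Intervention],
    budget_for_pool: float,
    rule: CoverageRule,
    params: ImpactParams,
    weights: ObjectiveWeights,
) -> Allocation:
    spend: dict[str, float] = {}
    lower: dict[str, float] = {}
    ceiling: dict[str, float] = {}
    binding: dict[str, tuple[bool, bool]] = {}
    objective = 0.0
    pool_ids = {iv.id for iv in pool}
    for iv in db.interventions:
        upper = effective_upper_bound(iv, rule, params)
        rate = score_rate(iv, weights, params)
        if iv.id in pool_ids:
            s = pool_spend.get(iv.id, 0.0)
            lo = 0.0
        else:
            s = estimate_current_spend(iv)
            lo = s
            upper = max(upper, s)  # fixed spend is honoured even above its impact cap
        spend[iv.id] = s
        lower[iv.id] = lo
        ceiling[iv.id] = upper
        binding[iv.id] = (
            math.isclose(s, lo, rel_tol=0.0, abs_tol=1e-9 + _REL_TOL * max(lo, 1.0)),
            math.isclose(s, upper, rel_tol=_REL_TOL, abs_tol=1e-9),
        )
        objective += min(s, effective_upper_bound(iv, rule, params)) * rate
    total_budget = budget_for_pool + sum(estimate_current_spend(iv) for iv in fixed) \
        if not getattr(config, "fixed_outside_budget", False) else budget_for_pool
    return Allocation(
        spend=spend,
        budget=total_budget,
        objective_value=objective,
        lower=lower,
        ceiling=ceiling,
        binding=binding,
    )


def optimize(db: CountryDatabook, config) -> Allocation:
    """Optimal allocation of the scenario budget across the portfolio.

    Greedy continuous-knapsack fill: non-fixed interventions are ranked
    by :func:`score_rate` (descending, ties broken by id ascending) and
    funded to their effective ceiling in rank order until the budget is
    exhausted.  For this model class — linear objective per intervention
    up to a single ceiling, one budget constraint — the greedy fill is
    the exact optimum; :func:`brute_force_optimize` and
    :func:`lp_optimize` verify this independently.

    Fixed-spend interventions keep their current spending; by default it
    is pre-committed inside the budget.
    """
    pool, fixed, budget_for_pool, rule, params, weights = _pool_setup(db, config)
    ranked = sorted(pool, key=lambda iv: (-score_rate(iv, weights, params), iv.id))
    remaining = budget_for_pool
    pool_spend: dict[str, float] = {}
    for iv in ranked:
        upper = effective_upper_bound(iv, rule, params)
        s = min(upper, remaining)
        pool_spend[iv.id] = s
        remaining -= s
        if remaining <= 0:
            remaining = max(remaining, 0.0)
    return _assemble(db, config, pool_spend, pool, fixed, budget_for_pool, rule, params, weights)


def brute_force_optimize(db: CountryDatabook, config, step: float) -> Allocation:
    """Exhaustive-search verification oracle on a discrete spending grid.

    Considers every feasible allocation in which each non-fixed
    intervention's spend is a multiple of ``step`` (the search is
    organised as exact dynamic programming over the grid, which visits
    the same solution set as naive enumeration).  The best grid objective
    is within ``max_rate * step * n`` of the continuous optimum.

    Limited to small instances: at most 6 non-fixed interventions and at
    most 10^6 budget grid nodes.
    """
    pool, fixed, budget_for_pool, rule, params, weights = _pool_setup(db, config)
    if len(pool) > 6:
        raise ValueError(f"brute force limited to <= 6 non-fixed interventions, got {len(pool)}")
    n_nodes = budget_for_pool / step
    if n_nodes > 1e6:
        raise ValueError(f"budget/step = {n_nodes:.3g} exceeds the 10^6 grid-node limit")

    n_units = int(math.floor(budget_for_pool / step + 1e-12))
    rates = [score_rate(iv, weights, params) for iv in pool]
    uppers = [effective_upper_bound(iv, rule, params) for iv in pool]
    max_units = [int(math.floor(u / step + 1e-12)) for u in uppers]

    # value[b] = best objective using the first i interventions and b budget units
    value = np.zeros(n_units + 1)
    choice = np.zeros((len(pool), n_units + 1), dtype=np.int64)
    for i, (rate, ku) in enumerate(zip(rates, max_units)):
        new = np.full(n_units + 1, -np.inf)
        for b in range(n_units + 1):
            for k in range(min(ku, b) + 1):
                cand = value[b - k] + rate * k * step
                if cand > new[b] + 1e-15:
                    new[b] = cand
                    choice[i, b] = k
        value = new

    pool_spend: dict[str, float] = {}
    b = int(np.argmax(value))
    for i in range(len(pool) - 1, -1, -1):
        k = int(choice[i, b])
        pool_spend[pool[i].id] = k * step
        b -= k
    return _assemble(db, config, pool_spend, pool, fixed, budget_for_pool, rule, params, weights)


def lp_optimize(db: CountryDatabook, config) -> Allocation:
    """Linear-programming verification oracle (scipy ``linprog``/HiGHS).

    Solves  max Σ rate_i x_i  s.t.  Σ x_i <= budget,  0 <= x_i <= upper_i
    over the non-fixed pool.  For the linear-up-to-ceiling model this is
    the same optimum the greedy fill attains.
    """
    pool, fixed, budget_for_pool, rule, params, weights = _pool_setup(db, config)
    rates = np.array([score_rate(iv, weights, params) for iv in pool])
    uppers = np.array([effective_upper_bound(iv, rule, params) for iv in pool])
    res = linprog(
        c=-rates,
        A_ub=np.ones((1, len(pool))),
        b_ub=[budget_for_pool],
        bounds=list(zip(np.zeros(len(pool)), uppers)),
        method="highs",
    )
    if not res.success:  # pragma: no cover - LP on a box is always feasible
        raise RuntimeError(f"LP solver failed: {res.message}")
    pool_spend = {iv.id: float(x) for iv, x in zip(pool, res.x)}
    return _assemble(db, config, pool_spend, pool, fixed, budget_for_pool, rule, params, weights)
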