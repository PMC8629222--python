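"""Greedy budget optimizer vs its exhaustive-grid and LP oracles."""

from __future__ import annotations

from dataclasses import replace
from types import SimpleNamespace

import pytest

from alloceff import (
    CountryDatabook,
    CoverageRule,
    ImpactParams,
    InfeasibleBudgetError,
    Intervention,
    ObjectiveWeights,
    ScenarioConfig,
    brute_force_optimize,
    lp_optimize,
    optimize,
    score_rate,
)
from alloceff.estimation import estimate_current_spend
from alloceff.optimizer import effective_upper_bound

from conftest import make_integer_instance

DEFAULT = ImpactParams()


def _cfg(budget: float, **kwargs) -> ScenarioConfig:
    return ScenarioConfig(budget=budget, **kwargs)


def _iv(iv_id, icer, ceiling_cost=10.0, pop=10.0, **overrides) -> Intervention:
    base = dict(
        id=iv_id,
        name=iv_id,
        care_package="pkg",
        platform_shares={"community": 1.0},
        unit_cost=ceiling_cost,
        icer=icer,
        target_population=pop,
        current_coverage=0.0,
        max_coverage=1.0,
    )
    base.update(overrides)
    return Intervention(**base)


class TestScoreRate:
    def test_pure_daly_weighting_is_dalys_per_dollar(self):
        iv = _iv("a", icer=200.0, frp_score=1.0, equity_score=1.0)
        assert score_rate(iv, ObjectiveWeights(1, 0, 0), DEFAULT) == pytest.approx(0.0035)

    def test_full_score_symmetry(self):
        """With unit FRP/equity scores, equal weights reproduce the DALY rate."""
        iv = _iv("a", icer=200.0, frp_score=1.0, equity_score=1.0)
        assert score_rate(iv, ObjectiveWeights(1, 1, 1), DEFAULT) == pytest.approx(0.0035)

    def test_zero_scores_scale_by_normalized_daly_weight(self):
        iv = _iv("a", icer=200.0, frp_score=0.0, equity_score=0.0)
        assert score_rate(iv, ObjectiveWeights(2, 1, 1), DEFAULT) == pytest.approx(0.0035 * 0.5)

    def test_weights_validation(self):
        with pytest.raises(ValueError):
            ObjectiveWeights(0, 0, 0)
        with pytest.raises(ValueError):
            ObjectiveWeights(-1, 1, 1)


class TestGreedyFill:
    def test_two_intervention_split(self):
        """Higher-rate intervention filled to its ceiling, remainder to the next."""
        db = CountryDatabook(
            interventions=[
                _iv("A", icer=0.7 / 2.0, ceiling_cost=6.0, pop=10.0),  # rate 2/unit, ceiling 60
                _iv("B", icer=0.7 / 1.0, ceiling_cost=10.0, pop=10.0),  # rate 1/unit, ceiling 100
            ],
            name="two",
        )
        alloc = optimize(db, _cfg(100.0))
        assert alloc.spend == pytest.approx({"A": 60.0, "B": 40.0})
        assert alloc.objective_value == pytest.approx(160.0)
        oracle = brute_force_optimize(db, _cfg(100.0), step=1.0)
        assert oracle.spend == pytest.approx(alloc.spend)

    def test_slack_budget_fills_every_ceiling(self, micro_db):
        alloc = optimize(micro_db, _cfg(10_000.0))
        for iv in micro_db:
            assert alloc.spend[iv.id] == pytest.approx(
                effective_upper_bound(iv, CoverageRule(), DEFAULT)
            )
            assert alloc.binding[iv.id][1]  # at ceiling

    def test_zero_budget_zero_allocation(self, micro_db):
        config = SimpleNamespace(
            budget=0.0,
            weights=ObjectiveWeights(),
            coverage_rule=CoverageRule(),
            impact_params=DEFAULT,
        )
        alloc = optimize(micro_db, config)
        assert all(s == 0.0 for s in alloc.spend.values())
        assert alloc.objective_value == 0.0

    def test_micro_portfolio_known_optimum(self, micro_db, micro_config):
        """Frozen optimum at budget 100: A and B at ceiling, 30 to C."""
        alloc = optimize(micro_db, micro_config)
        assert alloc.spend == pytest.approx({"A": 30.0, "B": 40.0, "C": 30.0, "D": 0.0, "E": 0.0})
        assert alloc.objective_value == pytest.approx(0.73)

    def test_determinism_and_id_tie_break(self):
        """Equal score rates are funded in id order, reproducibly."""
        db = CountryDatabook(
            interventions=[
                _iv("b", icer=100.0, ceiling_cost=5.0),
                _iv("a", icer=100.0, ceiling_cost=5.0),
            ],
            name="ties",
        )
        for _ in range(3):
            alloc = optimize(db, _cfg(60.0))
            assert alloc.spend == pytest.approx({"a": 50.0, "b": 10.0})

    def test_budget_conservation(self, micro_db):
        """Sum of spending equals the budget while ceilings are slack."""
        alloc = optimize(micro_db, _cfg(123.0))
        assert alloc.total_spend == pytest.approx(123.0)
        total_ceiling = sum(
            effective_upper_bound(iv, CoverageRule(), DEFAULT) for iv in micro_db
        )
        alloc = optimize(micro_db, _cfg(total_ceiling + 500.0))
        assert alloc.total_spend == pytest.approx(total_ceiling)

    def test_budget_monotonicity(self, micro_db):
        objs = [optimize(micro_db, _cfg(b)).objective_value for b in (20, 60, 100, 160, 260)]
        assert objs == sorted(objs)
        assert objs[0] < objs[-1]  # strictly increasing while ceilings are slack


class TestFixedSpend:
    def _db_with_fixed(self) -> CountryDatabook:
        fixed = _iv("F", icer=50.0, fixed_spend=True, current_spend_override=30.0)
        return CountryDatabook(interventions=[_iv("A", icer=100.0), fixed], name="fx")

    def test_fixed_inside_budget_is_precommitted(self):
        db = self._db_with_fixed()
        alloc = optimize(db, _cfg(80.0))
        assert alloc.spend["F"] == pytest.approx(30.0)
        assert alloc.spend["A"] == pytest.approx(50.0)  # 80 - 30 pre-committed
        assert alloc.total_spend == pytest.approx(80.0)

    def test_fixed_outside_budget_frees_the_pool(self):
        db = self._db_with_fixed()
        alloc = optimize(db, _cfg(80.0, fixed_outside_budget=True))
        assert alloc.spend["F"] == pytest.approx(30.0)
        assert alloc.spend["A"] == pytest.approx(80.0)

    def test_infeasible_when_fixed_exceeds_budget(self):
        db = self._db_with_fixed()
        with pytest.raises(InfeasibleBudgetError):
            optimize(db, _cfg(20.0))

    def test_config_fixed_ids_freeze_extra_interventions(self, micro_db, micro_config):
        from dataclasses import replace as dc_replace

        # give A some current spending so freezing it is observable
        ivs = [dc_replace(micro_db.interventions[0], current_coverage=0.5)] + list(
            micro_db.interventions[1:]
        )
        db = micro_db.replace_interventions(ivs)
        cfg = _cfg(100.0, fixed_ids=("A",))
        alloc = optimize(db, cfg)
        assert alloc.spend["A"] == pytest.approx(estimate_current_spend(db.get("A")))
        assert alloc.binding["A"][0]  # held at its (current-spend) lower bound


class TestOracles:
    @pytest.mark.parametrize("seed", range(20))
    def test_greedy_matches_grid_and_lp_oracles(self, seed):
        """On random small integer instances the greedy objective matches the
        unit-grid exhaustive optimum (within the grid bound) and the LP."""
        db, config = make_integer_instance(seed)
        greedy = optimize(db, config)
        grid = brute_force_optimize(db, config, step=1.0)
        lp = lp_optimize(db, config)
        rates = [score_rate(iv, config.weights, config.impact_params) for iv in db]
        bound = max(rates) * 1.0 * len(db.interventions)
        assert greedy.objective_value >= grid.objective_value - 1e-9
        assert greedy.objective_value - grid.objective_value <= bound + 1e-9
        assert greedy.objective_value == pytest.approx(lp.objective_value, rel=1e-6)

    def test_single_intervention_takes_whole_budget(self):
        db = CountryDatabook(interventions=[_iv("only", icer=100.0)], name="one")
        alloc = brute_force_optimize(db, _cfg(40.0), step=1.0)
        assert alloc.spend["only"] == pytest.approx(40.0)

    def test_brute_force_size_guards(self, micro_db):
        with pytest.raises(ValueError):
            brute_force_optimize(micro_db, _cfg(100.0), step=1e-6)
        big = CountryDatabook(
            interventions=[_iv(f"i{k}", icer=100.0) for k in range(7)], name="big"
        )
        with pytest.raises(ValueError):
            brute_force_optimize(big, _cfg(100.0), step=1.0)


class TestImprovementGuarantee:
    @pytest.mark.parametrize("seed", [3, 11])
    def test_optimum_dominates_projected_current_allocation(self, seed):
        from alloceff import GeneratorSpec, generate_country

        db = generate_country(GeneratorSpec(n_interventions=40, seed=seed))
        current = {iv.id: estimate_current_spend(iv) for iv in db}
        config = _cfg(sum(current.values()))
        alloc = optimize(db, config)
        rule, params, weights = config.coverage_rule, config.impact_params, config.weights
        projected = sum(
            min(current[iv.id], effective_upper_bound(iv, rule, params))
            * score_rate(iv, weights, params)
            for iv in db
        )
        assert alloc.objective_value >= projected - 1e-9
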