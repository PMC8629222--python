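"""Scenario runner and reporting: budget scenarios, aggregation by
delivery platform / care package / program, and comparison statistics.

A scenario fixes a budget (absolute, or a multiplier on current modelled
spending, e.g. ``1.38`` for a "+38%" envelope), objective weights, a
coverage rule and optional per-intervention or per-category target
coverage overrides.  Running it computes current spending and impact,
the optimized allocation, optimized impact, and spend/DALY aggregates
under both allocations for the three standard groupings.

All percentages are computed on full-precision values and only rounded
for display, so recomputing from a serialized result reproduces the
displayed integers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .databook import PLATFORMS, CountryDatabook, Intervention
from .estimation import UNASSIGNED_PROGRAM, estimate_current_spend
from .impact import CoverageRule, ImpactParams, impact_at_spend
from .optimizer import Allocation, ObjectiveWeights, optimize

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "ScenarioComparison",
    "run_scenario",
    "percent_change",
    "share_of_total",
    "compare_scenarios",
]

GROUPINGS = ("platform", "care_package", "program")


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything that defines one optimization scenario.

    budget:
        Total envelope.  Interpreted as absolute currency, or — when
        ``budget_is_multiplier`` — as a multiplier on the summed current
        spending of in-pool interventions (``1.38`` = a 38% increase).
    weights:
        Objective weights over DALYs, FRP and equity.
    coverage_rule / impact_params:
        Scale-up policy and impact-model knobs.
    fixed_ids:
        Extra intervention ids to hold at current spending (in addition
        to any flagged ``fixed_spend`` in the databook).
    fixed_outside_budget:
        If true, fixed spending sits outside the optimized envelope;
        default keeps it inside as a pre-committed amount.
    target_coverage_overrides:
        Map from intervention id, care-package or program label to a
        replacement ``max_coverage`` (e.g. "all NCD interventions
        -> 0.30").  Id matches take precedence over category matches.
    """

    budget: float
    weights: ObjectiveWeights = field(default_factory=ObjectiveWeights)
    coverage_rule: CoverageRule = field(default_factory=CoverageRule)
    impact_params: ImpactParams = field(default_factory=ImpactParams)
    budget_is_multiplier: bool = False
    fixed_ids: tuple[str, ...] = ()
    fixed_outside_budget: bool = False
    target_coverage_overrides: dict[str, float] = field(default_factory=dict)
    label: str = "scenario"

    def __post_init__(self) -> None:
        if not self.budget > 0:
            raise ValueError(f"budget must be > 0, got {self.budget}")
        for key, v in self.target_coverage_overrides.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"coverage override for {key!r} must lie in [0, 1], got {v}")
        object.__setattr__(self, "fixed_ids", tuple(self.fixed_ids))

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        return cls(
            budget=d["budget"],
            weights=ObjectiveWeights.from_dict(d.get("weights", {})),
            coverage_rule=CoverageRule.from_dict(d.get("coverage_rule", {})),
            impact_params=ImpactParams.from_dict(d.get("impact_params", {})),
            budget_is_multiplier=d.get("budget_is_multiplier", False),
            fixed_ids=tuple(d.get("fixed_ids", ())),
            fixed_outside_budget=d.get("fixed_outside_budget", False),
            target_coverage_overrides=dict(d.get("target_coverage_overrides", {})),
            label=d.get("label", "scenario"),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ScenarioConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return {
            "budget": self.budget,
            "weights": self.weights.to_dict(),
            "coverage_rule": self.coverage_rule.to_dict(),
            "impact_params": self.impact_params.to_dict(),
            "budget_is_multiplier": self.budget_is_multiplier,
            "fixed_ids": list(self.fixed_ids),
            "fixed_outside_budget": self.fixed_outside_budget,
            "target_coverage_overrides": dict(self.target_coverage_overrides),
            "label": self.label,
        }


@dataclass
class ScenarioResult:
    """Allocation plus impact accounting for one scenario run.

    ``aggregates`` maps grouping name (platform / care_package /
    program) to a table with current and optimized spend and DALYs per
    group; platform aggregation splits each intervention across
    platforms by its delivery shares.
    """

    config: ScenarioConfig
    databook_name: str
    intervention_ids: tuple[str, ...]
    allocation: Allocation
    current_spend: dict[str, float]
    current_impact: dict[str, float]
    optimized_impact: dict[str, float]
    aggregates: dict[str, pd.DataFrame]

    @property
    def totals(self) -> dict[str, float]:
        return {
            "current_spend": sum(self.current_spend.values()),
            "current_dalys": sum(self.current_impact.values()),
            "optimized_spend": self.allocation.total_spend,
            "optimized_dalys": sum(self.optimized_impact.values()),
        }


def _apply_overrides(db: CountryDatabook, overrides: dict[str, float]) -> CountryDatabook:
    """Return a databook copy with ``max_coverage`` overrides applied.

    A key matching an intervention id wins over a key matching its
    care-package or program label.
    """
    if not overrides:
        return db
    new: list[Intervention] = []
    for iv in db.interventions:
        if iv.id in overrides:
            new.append(replace(iv, max_coverage=overrides[iv.id]))
        elif iv.care_package in overrides:
            new.append(replace(iv, max_coverage=overrides[iv.care_package]))
        elif iv.program is not None and iv.program in overrides:
            new.append(replace(iv, max_coverage=overrides[iv.program]))
        else:
            new.append(iv)
    return db.replace_interventions(new)


def _aggregate(
    db: CountryDatabook,
    spend_cur: dict[str, float],
    dalys_cur: dict[str, float],
    spend_opt: dict[str, float],
    dalys_opt: dict[str, float],
) -> dict[str, pd.DataFrame]:
    """Spend/DALY tables per grouping, under current and optimized allocations.

    Platform rows are weighted by each intervention's delivery shares, so
    every grouping's columns sum to the same portfolio totals.
    """
    out: dict[str, pd.DataFrame] = {}
    cols = ("spend_current", "dalys_current", "spend_optimized", "dalys_optimized")

    acc: dict[str, dict[str, float]] = {}
    for iv in db.interventions:
        vals = (spend_cur[iv.id], dalys_cur[iv.id], spend_opt[iv.id], dalys_opt[iv.id])
        for platform, share in iv.platform_shares.items():
            row = acc.setdefault(platform, dict.fromkeys(cols, 0.0))
            for c, v in zip(cols, vals):
                row[c] += share * v
    out["platform"] = (
        pd.DataFrame.from_dict(acc, orient="index", columns=list(cols))
        .reindex([p for p in PLATFORMS if p in acc])
        .rename_axis("platform")
    )

    for grouping, key in (
        ("care_package", lambda iv: iv.care_package),
        ("program", lambda iv: iv.program or UNASSIGNED_PROGRAM),
    ):
        acc = {}
        for iv in db.interventions:
            row = acc.setdefault(key(iv), dict.fromkeys(cols, 0.0))
            row["spend_current"] += spend_cur[iv.id]
            row["dalys_current"] += dalys_cur[iv.id]
            row["spend_optimized"] += spend_opt[iv.id]
            row["dalys_optimized"] += dalys_opt[iv.id]
        out[grouping] = (
            pd.DataFrame.from_dict(acc, orient="index", columns=list(cols))
            .sort_index()
            .rename_axis(grouping)
        )
    return out


def run_scenario(db: CountryDatabook, config: ScenarioConfig) -> ScenarioResult:
    """Run one budget scenario end to end.

    Applies the coverage overrides, computes current spending and the
    impact it buys, optimizes the budget, prices the optimized impact
    with the same impact model (so current and optimized are strictly
    comparable), and fills the grouped aggregates.
    """
    db = _apply_overrides(db, config.target_coverage_overrides)
    rule, params = config.coverage_rule, config.impact_params

    current_spend = {iv.id: estimate_current_spend(iv) for iv in db.interventions}
    current_impact = {
        iv.id: impact_at_spend(iv, current_spend[iv.id], rule, params) for iv in db.interventions
    }
    allocation = optimize(db, config)
    optimized_impact = {
        iv.id: impact_at_spend(iv, allocation.spend[iv.id], rule, params) for iv in db.interventions
    }
    aggregates = _aggregate(db, current_spend, current_impact, allocation.spend, optimized_impact)
    return ScenarioResult(
        config=config,
        databook_name=db.name,
        intervention_ids=tuple(db.ids),
        allocation=allocation,
        current_spend=current_spend,
        current_impact=current_impact,
        optimized_impact=optimized_impact,
        aggregates=aggregates,
    )


def percent_change(before: float, after: float) -> float:
    """Percent change from ``before`` to ``after``; ``nan`` when undefined.

    Returned at full precision — reports round to the nearest integer
    for display.  E.g. 120,000 -> 151,000 DALYs is +25.83%, displayed
    as 26%.
    """
    if not before > 0:
        return math.nan
    return (after - before) / before * 100.0


def share_of_total(part: float, total: float) -> float:
    """``part`` as a percentage of ``total``; ``nan`` when total <= 0."""
    if not total > 0:
        return math.nan
    return part / total * 100.0


@dataclass
class ScenarioComparison:
    """Side-by-side scenario totals and per-group deltas.

    ``totals`` has one row per scenario; ``by_group[g]`` holds, per group
    in grouping ``g``, optimized spend and DALYs per scenario plus the
    change of each later scenario relative to the first, sorted by DALY
    gain.
    """

    totals: pd.DataFrame
    by_group: dict[str, pd.DataFrame]


def compare_scenarios(results: list[ScenarioResult]) -> ScenarioComparison:
    """Tabulate >= 2 scenario results run on the same databook."""
    if len(results) < 2:
        raise ValueError("need at least two scenario results to compare")
    first = results[0]
    for r in results[1:]:
        if r.databook_name != first.databook_name or r.intervention_ids != first.intervention_ids:
            raise ValueError("scenario results were not produced from the same databook")

    totals = pd.DataFrame(
        [{"label": r.config.label, **r.totals} for r in results]
    ).set_index("label")

    by_group: dict[str, pd.DataFrame] = {}
    for grouping in GROUPINGS:
        frames = []
        for r in results:
            agg = r.aggregates[grouping]
            frames.append(
                agg[["spend_optimized", "dalys_optimized"]].rename(
                    columns={
                        "spend_optimized": f"spend[{r.config.label}]",
                        "dalys_optimized": f"dalys[{r.config.label}]",
                    }
                )
            )
        table = pd.concat(frames, axis=1).fillna(0.0)
        base = results[0].config.label
        for r in results[1:]:
            lab = r.config.label
            table[f"spend_delta[{lab}]"] = table[f"spend[{lab}]"] - table[f"spend[{base}]"]
            table[f"dalys_delta[{lab}]"] = table[f"dalys[{lab}]"] - table[f"dalys[{base}]"]
            table[f"dalys_pct[{lab}]"] = [
                percent_change(b, a)
                for b, a in zip(table[f"dalys[{base}]"], table[f"dalys[{lab}]"])
            ]
        last = results[-1].config.label
        sort_col = f"dalys_delta[{last}]"
        by_group[grouping] = table.sort_values(sort_col, ascending=False)
    return ScenarioComparison(totals=totals, by_group=by_group)
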