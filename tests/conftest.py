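"""Shared fixtures: the micro portfolio and random integer instances."""

from __future__ import annotations

import numpy as np
import pytest

from alloceff import (
    CountryDatabook,
    Intervention,
    ScenarioConfig,
    micro_example,
)


@pytest.fixture
def micro_db() -> CountryDatabook:
    return micro_example()


@pytest.fixture
def micro_config() -> ScenarioConfig:
    return ScenarioConfig(budget=100.0, label="micro-base")


def make_integer_instance(seed: int, n_max: int = 5) -> tuple[CountryDatabook, ScenarioConfig]:
    """A small random portfolio with integer costs, populations and budget.

    Zero current coverage and unit max coverage make every spending
    ceiling the integer product unit_cost x population, so an exhaustive
    search on a unit spending grid brackets the continuous optimum.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, n_max + 1))
    interventions = []
    for i in range(n):
        unit_cost = float(rng.integers(1, 6))
        population = float(rng.integers(2, 10))
        burden = None
        if rng.uniform() < 0.3:
            burden = float(rng.integers(1, 50))
        interventions.append(
            Intervention(
                id=f"x{i}",
                name=f"instance iv {i}",
                care_package="pkg",
                platform_shares={"community": 1.0},
                unit_cost=unit_cost,
                icer=float(rng.integers(5, 200)),
                target_population=population,
                current_coverage=0.0,
                max_coverage=1.0,
                frp_score=float(rng.choice([0.0, 0.5, 1.0])),
                equity_score=float(rng.choice([0.0, 0.5, 1.0])),
                attributable_burden=burden,
            )
        )
    db = CountryDatabook(interventions=interventions, name=f"instance-{seed}")
    total_ceiling = sum(iv.unit_cost * iv.target_population for iv in interventions)
    budget = float(rng.integers(1, max(2, int(0.8 * total_ceiling))))
    budget = min(budget, 120.0)
    if rng.uniform() < 0.5:
        weights = {"w_dalys": 1.0, "w_frp": 0.0, "w_equity": 0.0}
    else:
        weights = {
            "w_dalys": float(rng.integers(1, 4)),
            "w_frp": float(rng.integers(0, 3)),
            "w_equity": float(rng.integers(0, 3)),
        }
    config = ScenarioConfig.from_dict(
        {"budget": budget, "weights": weights, "label": f"instance-{seed}"}
    )
    return db, config
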