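"""Synthetic country databooks for testing and demonstration.

The generator emulates the statistical structure of a real national
intervention portfolio — on the order of 135–179 interventions spread
over ~19–21 care packages and five delivery platforms — without
attempting to mimic any particular country's data: unit costs and ICERs
are log-normal (strictly positive, right-skewed, spanning orders of
magnitude as cost-effectiveness league tables do), coverages are
beta-distributed on [0, 1], and a subset of interventions carries an
attributable-burden cap or a fixed-spend flag.

``micro_example`` returns a fixed five-intervention portfolio small
enough for its optimal allocation to be known exhaustively; it anchors
the optimizer tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .databook import PLATFORMS, CountryDatabook, Intervention

__all__ = ["GeneratorSpec", "generate_country", "micro_example"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Distributional recipe for a synthetic country portfolio.

    Defaults are sized to a mid-sized national portfolio: 135
    interventions in 19 care packages; unit costs centred near $12 per
    person-year and ICERs near $400 per DALY averted, both with wide
    log-normal spread; coverage beta(2, 2) (symmetric, mostly mid-range);
    half the interventions linked to an attributable disease burden; 10%
    of lines held fixed (spending outside the optimizer's reach).
    """

    n_interventions: int = 135
    seed: int = 0
    unit_cost_log_mean: float = 2.5  # exp(2.5) ~ $12 per person-year
    unit_cost_log_sd: float = 1.0
    icer_log_mean: float = 6.0  # exp(6) ~ $400 per DALY averted
    icer_log_sd: float = 1.2
    coverage_alpha: float = 2.0
    coverage_beta: float = 2.0
    population_range: tuple[float, float] = (1_000.0, 500_000.0)
    burden_link_probability: float = 0.5
    platform_mixture_weights: tuple[float, ...] = (0.10, 0.25, 0.30, 0.20, 0.15)
    n_care_packages: int = 19
    fraction_fixed: float = 0.10

    def __post_init__(self) -> None:
        if self.n_interventions < 1:
            raise ValueError("n_interventions must be >= 1")
        if self.unit_cost_log_sd < 0 or self.icer_log_sd < 0:
            raise ValueError("log-sd parameters must be >= 0")
        if self.coverage_alpha <= 0 or self.coverage_beta <= 0:
            raise ValueError("coverage beta-distribution parameters must be > 0")
        lo, hi = self.population_range
        if not 0 <= lo <= hi:
            raise ValueError(f"population_range must satisfy 0 <= lo <= hi, got {self.population_range}")
        if not 0.0 <= self.burden_link_probability <= 1.0:
            raise ValueError("burden_link_probability must lie in [0, 1]")
        if len(self.platform_mixture_weights) != len(PLATFORMS):
            raise ValueError(f"platform_mixture_weights must have {len(PLATFORMS)} entries")
        if any(w < 0 for w in self.platform_mixture_weights) or sum(self.platform_mixture_weights) <= 0:
            raise ValueError("platform_mixture_weights must be non-negative and not all zero")
        if not 0.0 <= self.fraction_fixed < 1.0:
            raise ValueError("fraction_fixed must lie in [0, 1)")
        if self.n_care_packages < 1:
            raise ValueError("n_care_packages must be >= 1")


def _platform_shares(rng: np.random.Generator, weights: np.ndarray) -> dict[str, float]:
    """One to three platforms per intervention; shares sum to 1 exactly."""
    n_platforms = rng.choice([1, 2, 3], p=[0.6, 0.3, 0.1])
    chosen = rng.choice(len(PLATFORMS), size=n_platforms, replace=False, p=weights)
    if n_platforms == 1:
        return {PLATFORMS[int(chosen[0])]: 1.0}
    raw = rng.dirichlet(np.ones(n_platforms))
    raw = raw / raw.sum()
    shares = {PLATFORMS[int(i)]: float(v) for i, v in zip(chosen, raw)}
    # force exact unit sum after float division
    k = next(iter(shares))
    shares[k] += 1.0 - sum(shares.values())
    return shares


def generate_country(spec: GeneratorSpec) -> CountryDatabook:
    """Draw a synthetic databook; deterministic given ``spec.seed``.

    Every generated databook passes :func:`alloceff.databook.validate_databook`.
    Attributable burdens, where linked, are drawn around each
    intervention's untruncated maximum impact (uniform 0.5x–1.5x), so
    burden caps bind for roughly half the linked interventions.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_interventions
    w = np.asarray(spec.platform_mixture_weights, dtype=float)
    w = w / w.sum()

    unit_cost = np.exp(rng.normal(spec.unit_cost_log_mean, spec.unit_cost_log_sd, n))
    icer = np.exp(rng.normal(spec.icer_log_mean, spec.icer_log_sd, n))
    coverage = rng.beta(spec.coverage_alpha, spec.coverage_beta, n)
    lo, hi = spec.population_range
    population = rng.uniform(lo, hi, n)
    frp = rng.uniform(0.0, 1.0, n)
    equity = rng.uniform(0.0, 1.0, n)
    burden_linked = rng.uniform(size=n) < spec.burden_link_probability
    burden_scale = rng.uniform(0.5, 1.5, n)
    care_pkg = rng.integers(0, spec.n_care_packages, n)
    n_fixed = int(round(spec.fraction_fixed * n))
    # never fix everything: the optimizer needs a pool
    n_fixed = min(n_fixed, n - 1)
    fixed_idx = set(rng.choice(n, size=n_fixed, replace=False).tolist()) if n_fixed else set()

    interventions = []
    for i in range(n):
        cur = float(coverage[i])
        max_cov = max(0.8, cur)
        burden = None
        if burden_linked[i]:
            # around the untruncated max impact at default 30% quality reduction
            full_impact = unit_cost[i] * population[i] * max_cov * 0.7 / icer[i]
            burden = float(full_impact * burden_scale[i])
        interventions.append(
            Intervention(
                id=f"iv{i:03d}",
                name=f"synthetic intervention {i}",
                care_package=f"package_{care_pkg[i]:02d}",
                program=f"program_{care_pkg[i] % max(1, spec.n_care_packages // 2):02d}",
                platform_shares=_platform_shares(rng, w),
                unit_cost=float(unit_cost[i]),
                icer=float(icer[i]),
                target_population=float(population[i]),
                current_coverage=cur,
                max_coverage=max_cov,
                frp_score=float(frp[i]),
                equity_score=float(equity[i]),
                attributable_burden=burden,
                fixed_spend=i in fixed_idx,
            )
        )
    return CountryDatabook(
        interventions=interventions,
        name=f"synthetic-{spec.seed}",
        currency_year=2019,
        deflators={2019: 100.0},
    )


def micro_example() -> CountryDatabook:
    """A fixed five-intervention portfolio with a known optimal allocation.

    Integer unit costs and populations, zero current coverage and unit
    max coverage give integer spending ceilings (A..E: 30, 40, 50, 60,
    80) and strictly decreasing DALY rates, so the pure-DALY optimum at
    budget 100 is A and B at ceiling plus 30 to C — verified against the
    exhaustive grid oracle in the test suite.
    """
    rows = [
        # id, icer, unit_cost, population, burden
        ("A", 70.0, 3.0, 10.0, None),  # ceiling 30, rate 0.0100
        ("B", 100.0, 4.0, 10.0, None),  # ceiling 40, rate 0.0070
        ("C", 140.0, 5.0, 10.0, None),  # ceiling 50, rate 0.0050
        ("D", 200.0, 6.0, 10.0, None),  # ceiling 60, rate 0.0035
        ("E", 350.0, 8.0, 10.0, None),  # ceiling 80, rate 0.0020
    ]
    platforms = ("community", "health_center", "first_level_hospital", "referral_hospital", "population")
    interventions = [
        Intervention(
            id=iv_id,
            name=f"micro intervention {iv_id}",
            care_package=f"package_{i % 2}",
            program=f"program_{i % 2}",
            platform_shares={platforms[i]: 1.0},
            unit_cost=cost,
            icer=icer,
            target_population=pop,
            current_coverage=0.0,
            max_coverage=1.0,
            frp_score=0.5,
            equity_score=0.5,
            attributable_burden=burden,
        )
        for i, (iv_id, icer, cost, pop, burden) in enumerate(rows)
    ]
    return CountryDatabook(interventions=interventions, name="micro", currency_year=2019)
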