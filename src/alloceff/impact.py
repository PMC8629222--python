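"""Per-intervention impact model: effective cost-effectiveness, coverage
rules, investment ceilings and maximum potential impact (MPI).

The model is deliberately linear and static.  Each intervention converts
spending into DALYs averted at a constant rate — its ICER discounted by a
*quality reduction* factor ``r`` reflecting that real-world effect sizes
at scale fall short of trial estimates (default 30%) — up to a spending
ceiling implied by its allowed maximum coverage, and optionally capped by
the disease burden it can address:

    effective_ce = (1 - r) / ICER                      [DALYs per currency]
    ceiling      = unit_cost x population x allowed_max_coverage
    MPI          = min(ceiling x effective_ce, attributable_burden)
    impact(s)    = min(min(s, ceiling) x effective_ce, MPI)

``impact_at_spend`` is therefore piecewise linear, non-decreasing and
concave in spend, with a single kink at the binding cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .databook import Intervention
from .estimation import estimate_current_spend

__all__ = [
    "ImpactParams",
    "CoverageRule",
    "effective_ce",
    "allowed_max_coverage",
    "spend_ceiling",
    "max_potential_impact",
    "impact_at_spend",
]

DEFAULT_QUALITY_REDUCTION = 0.30


@dataclass(frozen=True)
class ImpactParams:
    """Knobs of the impact model.

    quality_reduction:
        Fractional discount ``r`` in [0, 1) applied to intervention effect
        (not cost); default 0.30.
    burden_cap_enabled:
        Whether attributable-burden caps bind (default true).  Disabling
        lets datasets without burden links reproduce pure spend/ICER
        arithmetic.
    """

    quality_reduction: float = DEFAULT_QUALITY_REDUCTION
    burden_cap_enabled: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.quality_reduction < 1.0:
            raise ValueError(f"quality_reduction must lie in [0, 1), got {self.quality_reduction}")

    @classmethod
    def from_dict(cls, d: dict) -> "ImpactParams":
        return cls(
            quality_reduction=d.get("quality_reduction", DEFAULT_QUALITY_REDUCTION),
            burden_cap_enabled=d.get("burden_cap_enabled", True),
        )

    def to_dict(self) -> dict:
        return {
            "quality_reduction": self.quality_reduction,
            "burden_cap_enabled": self.burden_cap_enabled,
        }


@dataclass(frozen=True)
class CoverageRule:
    """Policy constraint on how far coverage may scale up.

    mode:
        ``"unconstrained"`` — the intervention's own ``max_coverage`` is
        the target;
        ``"absolute_increase"`` — coverage may rise by at most ``delta``
        above baseline (e.g. a "10 percentage points only" scenario);
        ``"tiered"`` — the cap depends on which baseline stratum the
        current coverage falls in, e.g. cap 90% below a 90% baseline,
        95% for baselines in [90%, 95%), 100% at or above 95%.
    tiers:
        For tiered mode: ``(baseline_upper_bound, cap)`` pairs sorted by
        bound; a baseline belongs to the first tier whose upper bound
        strictly exceeds it (half-open intervals ``[lower, upper)``).
    """

    mode: str = "unconstrained"
    delta: float = 0.0
    tiers: Sequence[tuple[float, float]] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.mode not in {"unconstrained", "absolute_increase", "tiered"}:
            raise ValueError(f"unknown coverage rule mode {self.mode!r}")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must lie in [0, 1], got {self.delta}")
        tiers = tuple((float(b), float(c)) for b, c in self.tiers)
        if any(not 0.0 <= c <= 1.0 for _, c in tiers):
            raise ValueError("tier caps must lie in [0, 1]")
        if list(tiers) != sorted(tiers, key=lambda t: t[0]):
            raise ValueError("tiers must be sorted by baseline upper bound")
        if self.mode == "tiered" and not tiers:
            raise ValueError("tiered mode requires at least one tier")
        object.__setattr__(self, "tiers", tiers)

    @classmethod
    def from_dict(cls, d: dict) -> "CoverageRule":
        return cls(
            mode=d.get("mode", "unconstrained"),
            delta=d.get("delta", 0.0),
            tiers=tuple(tuple(t) for t in d.get("tiers", ())),
        )

    def to_dict(self) -> dict:
        out: dict = {"mode": self.mode}
        if self.mode == "absolute_increase":
            out["delta"] = self.delta
        if self.mode == "tiered":
            out["tiers"] = [list(t) for t in self.tiers]
        return out


def effective_ce(icer: float, params: ImpactParams) -> float:
    """DALYs averted per currency unit after the quality reduction.

    ``(1 - r) / ICER`` — e.g. an ICER of $200/DALY with the default 30%
    reduction yields 0.0035 DALYs per dollar.
    """
    if not icer > 0:
        raise ValueError(f"icer must be > 0, got {icer}")
    return (1.0 - params.quality_reduction) / icer


def allowed_max_coverage(iv: Intervention, rule: CoverageRule) -> float:
    """Coverage the intervention may scale to under the policy rule.

    Always capped by the intervention's own ``max_coverage`` and floored
    at ``current_coverage`` (a rule never forces disinvestment; the
    optimizer's lower bounds govern that separately).
    """
    if rule.mode == "unconstrained":
        raw = iv.max_coverage
    elif rule.mode == "absolute_increase":
        raw = min(iv.max_coverage, iv.current_coverage + rule.delta)
    else:  # tiered
        cap = rule.tiers[-1][1]
        for bound, tier_cap in rule.tiers:
            if iv.current_coverage < bound:
                cap = tier_cap
                break
        raw = min(iv.max_coverage, cap)
    return max(raw, iv.current_coverage)


def spend_ceiling(iv: Intervention, rule: CoverageRule) -> float:
    """Maximum justifiable annual spending on the intervention.

    Full scale-up cost ``unit_cost x target_population x allowed
    coverage``.  A fixed-spend intervention's ceiling is exactly its
    current spending — it cannot absorb more.
    """
    if iv.fixed_spend:
        return estimate_current_spend(iv)
    return iv.unit_cost * iv.target_population * allowed_max_coverage(iv, rule)


def max_potential_impact(
    iv: Intervention,
    rule: CoverageRule,
    params: ImpactParams,
) -> float:
    """Maximum DALYs the intervention can avert per year (MPI).

    Spending at the ceiling converted at the effective cost-effectiveness
    rate, truncated at the attributable disease burden when one is linked
    and burden caps are enabled.
    """
    mpi = spend_ceiling(iv, rule) * effective_ce(iv.icer, params)
    if params.burden_cap_enabled and iv.attributable_burden is not None:
        mpi = min(mpi, iv.attributable_burden)
    return mpi


def impact_at_spend(
    iv: Intervention,
    spend: float,
    rule: CoverageRule,
    params: ImpactParams,
) -> float:
    """DALYs averted by spending ``spend`` on the intervention.

    Linear below the caps; saturates at the MPI once either the spending
    ceiling or the burden cap binds.
    """
    if spend < 0:
        raise ValueError(f"spend must be >= 0, got {spend}")
    ceiling = spend_ceiling(iv, rule)
    raw = min(spend, ceiling) * effective_ce(iv.icer, params)
    return min(raw, max_potential_impact(iv, rule, params))
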