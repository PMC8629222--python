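"""Impact model: effective cost-effectiveness, coverage rules, ceilings, MPI."""

from __future__ import annotations

from dataclasses import replace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alloceff import (
    CoverageRule,
    ImpactParams,
    Intervention,
    allowed_max_coverage,
    effective_ce,
    impact_at_spend,
    max_potential_impact,
    spend_ceiling,
)

DEFAULT = ImpactParams()
UNCONSTRAINED = CoverageRule()

#: The three-stratum scale-up rule: cap 90% below a 90% baseline,
#: 95% for baselines in [90%, 95%), 100% at or above 95%.
TIERED = CoverageRule(mode="tiered", tiers=((0.90, 0.90), (0.95, 0.95), (1.01, 1.00)))


def _iv(**overrides) -> Intervention:
    base = dict(
        id="t",
        name="test iv",
        care_package="pkg",
        platform_shares={"community": 1.0},
        unit_cost=10.0,
        icer=200.0,
        target_population=1000.0,
        current_coverage=0.5,
        max_coverage=0.8,
    )
    base.update(overrides)
    return Intervention(**base)


@pytest.mark.parametrize(
    "icer,r,expected",
    [(200.0, 0.3, 0.0035), (70.0, 0.3, 0.01), (123.0, 0.0, 1 / 123.0)],
)
def test_effective_ce_discounts_the_effect(icer, r, expected):
    assert effective_ce(icer, ImpactParams(quality_reduction=r)) == pytest.approx(expected)


def test_effective_ce_rejects_nonpositive_icer():
    with pytest.raises(ValueError):
        effective_ce(0.0, DEFAULT)


@pytest.mark.parametrize(
    "baseline,expected",
    [(0.85, 0.90), (0.92, 0.95), (0.96, 1.00), (0.90, 0.95), (0.95, 1.00)],
)
def test_tiered_rule_reproduces_baseline_strata(baseline, expected):
    """Tier membership is half-open: a 90% baseline falls in the 90-94 tier."""
    iv = _iv(current_coverage=baseline, max_coverage=1.0)
    assert allowed_max_coverage(iv, TIERED) == pytest.approx(expected)


def test_absolute_increase_rule_caps_the_step():
    iv = _iv(current_coverage=0.5, max_coverage=0.8)
    rule = CoverageRule(mode="absolute_increase", delta=0.10)
    assert allowed_max_coverage(iv, rule) == pytest.approx(0.60)


def test_unconstrained_rule_uses_intervention_target():
    assert allowed_max_coverage(_iv(), UNCONSTRAINED) == pytest.approx(0.8)


def test_allowed_coverage_floored_at_baseline():
    """A rule never drags the target below the current coverage."""
    iv = _iv(current_coverage=0.85, max_coverage=0.85)
    assert allowed_max_coverage(iv, TIERED) == pytest.approx(0.85)
    rule = CoverageRule(mode="absolute_increase", delta=0.0)
    assert allowed_max_coverage(iv, rule) == pytest.approx(0.85)


def test_spend_ceiling_full_scale_up_product():
    assert spend_ceiling(_iv(), UNCONSTRAINED) == pytest.approx(8000.0)


def test_spend_ceiling_of_fixed_intervention_is_current_spend():
    iv = _iv(fixed_spend=True, current_spend_override=5000.0)
    assert spend_ceiling(iv, UNCONSTRAINED) == pytest.approx(5000.0)


def test_spend_ceiling_degenerate_when_target_equals_baseline():
    iv = _iv(current_coverage=0.8, max_coverage=0.8)
    assert spend_ceiling(iv, UNCONSTRAINED) == pytest.approx(10.0 * 1000.0 * 0.8)


@pytest.mark.parametrize(
    "burden,expected",
    [(None, 28.0), (20.0, 20.0), (100.0, 28.0)],
)
def test_max_potential_impact_burden_cap(burden, expected):
    """MPI is ceiling x effective rate, truncated at the linked burden."""
    iv = _iv(attributable_burden=burden)
    assert max_potential_impact(iv, UNCONSTRAINED, DEFAULT) == pytest.approx(expected)


def test_burden_cap_can_be_disabled():
    iv = _iv(attributable_burden=20.0)
    params = ImpactParams(burden_cap_enabled=False)
    assert max_potential_impact(iv, UNCONSTRAINED, params) == pytest.approx(28.0)


@pytest.mark.parametrize(
    "spend,expected",
    [(0.0, 0.0), (4000.0, 14.0), (8000.0, 28.0), (10000.0, 28.0)],
)
def test_impact_at_spend_linear_then_saturated(spend, expected):
    assert impact_at_spend(_iv(), spend, UNCONSTRAINED, DEFAULT) == pytest.approx(expected)


def test_impact_equals_mpi_at_and_beyond_ceiling():
    iv = _iv(attributable_burden=20.0)
    mpi = max_potential_impact(iv, UNCONSTRAINED, DEFAULT)
    for spend in (8000.0, 9000.0, 1e7):
        assert impact_at_spend(iv, spend, UNCONSTRAINED, DEFAULT) == pytest.approx(mpi)


@given(
    s1=st.floats(0, 20_000),
    s2=st.floats(0, 20_000),
    lam=st.floats(0, 1),
    burden=st.one_of(st.none(), st.floats(1.0, 50.0)),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_impact_curve_monotone_and_concave(s1, s2, lam, burden):
    """impact_at_spend is non-decreasing and midpoint-concave in spend."""
    iv = _iv(attributable_burden=burden)

    def f(s):
        return impact_at_spend(iv, s, UNCONSTRAINED, DEFAULT)

    lo, hi = sorted((s1, s2))
    assert f(lo) <= f(hi) + 1e-9
    mid = lam * s1 + (1 - lam) * s2
    assert f(mid) >= lam * f(s1) + (1 - lam) * f(s2) - 1e-9


@pytest.mark.parametrize("k", [0.5, 2.0, 10.0])
def test_icer_scaling_divides_impact_exactly(k):
    """Multiplying every ICER by k divides every impact by k."""
    iv = _iv(attributable_burden=None)
    scaled = replace(iv, icer=iv.icer * k)
    for spend in (0.0, 3000.0, 8000.0, 12000.0):
        base = impact_at_spend(iv, spend, UNCONSTRAINED, DEFAULT)
        assert impact_at_spend(scaled, spend, UNCONSTRAINED, DEFAULT) == pytest.approx(base / k, rel=1e-12)


def test_zero_quality_reduction_recovers_spend_over_icer():
    params = ImpactParams(quality_reduction=0.0, burden_cap_enabled=False)
    iv = _iv(attributable_burden=5.0)
    for spend in (100.0, 2500.0, 8000.0):
        assert impact_at_spend(iv, spend, UNCONSTRAINED, params) == pytest.approx(spend / iv.icer)


def test_rule_and_params_round_trip_through_dicts():
    for rule in (UNCONSTRAINED, TIERED, CoverageRule(mode="absolute_increase", delta=0.1)):
        assert CoverageRule.from_dict(rule.to_dict()) == rule
    params = ImpactParams(quality_reduction=0.2, burden_cap_enabled=False)
    assert ImpactParams.from_dict(params.to_dict()) == params


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(mode="bogus"),
        dict(mode="absolute_increase", delta=1.5),
        dict(mode="tiered", tiers=()),
        dict(mode="tiered", tiers=((0.95, 0.95), (0.90, 0.90))),
        dict(mode="tiered", tiers=((0.9, 1.2),)),
    ],
)
def test_invalid_coverage_rules_rejected(kwargs):
    with pytest.raises(ValueError):
        CoverageRule(**kwargs)


def test_invalid_quality_reduction_rejected():
    with pytest.raises(ValueError):
        ImpactParams(quality_reduction=1.0)
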