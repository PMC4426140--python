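import math

import pytest

import introgress as ig
from introgress.stochastic import NoSupercriticalHaplotype

from conftest import make_scenario


def test_own_type_establishment():
    assert ig.own_type_establishment(0.01, 0.003) == pytest.approx(0.007 / 0.997)
    assert ig.own_type_establishment(0.01, 0.01) == 0.0
    assert ig.own_type_establishment(-0.02, 0.003) == 0.0
    with pytest.raises(ValueError):
        ig.own_type_establishment(0.5, 1.0)


def test_supercritical_founder_is_delta(worked_example):
    dist = ig.rescue_distribution(worked_example)
    assert dist.P == {(0, 1): 1.0}
    assert dist(0, 1) == 1.0
    assert dist(0, 0) == 0.0


def test_rescue_normalization_and_support():
    scn = make_scenario(
        right=[0.01, 0.075], left=[0.082], rho=1e-4, sigma_ben=0.08
    )
    dist = ig.rescue_distribution(scn)
    assert sum(dist.P.values()) == pytest.approx(1.0, abs=1e-12)
    # only supercritical classes can be rescue types
    for (i, j), p in dist.support().items():
        assert ig.is_supercritical(scn, i, j)


def test_rescue_tight_linkage_limit():
    # Eq.-55-type limit: weights proportional to r * sigma for tight linkage
    scn = make_scenario(right=[0.005, 0.095], rho=1e-6, sigma_ben=0.075)
    dist = ig.rescue_distribution(scn)
    s00, s01 = 0.075, 0.07
    expect01 = s01 / (s00 + s01)
    assert dist(0, 1) == pytest.approx(expect01, rel=1e-3)
    assert dist(0, 0) == pytest.approx(1 - expect01, rel=1e-3)


def test_rescue_with_unlinked_alleles_reports_f0():
    scn = make_scenario(
        right=[0.105], right_iv=[1e-4], unlinked=0.02, F=3, sigma_ben=0.075
    )
    dist = ig.rescue_distribution(scn)
    assert sum(dist.P.values()) == pytest.approx(1.0, abs=1e-12)
    assert set(dist.support()) == {(0, 0)}


def test_no_supercritical_haplotype_raises():
    # (0,1) and (0,2) are subcritical and the inner interval never
    # recombines, so the fit (0,0) class is unreachable from the founder
    sel = ig.build_additive_selection(0.075, right_effects=[0.08, 0.01])
    rec = ig.build_interval_recombination(right_intervals=[0.0, 0.01])
    scn = ig.Scenario(
        N=1000, architecture=sel.architecture, selection=sel, recombination=rec
    )
    with pytest.raises(NoSupercriticalHaplotype):
        ig.rescue_distribution(scn)


def test_conditional_establishment_worked_example(worked_example):
    p = ig.conditional_establishment_supercritical(worked_example)
    # (sigma - r)/(1 - r) / (1 - Q) = 0.0070211/0.0104427
    assert p == pytest.approx(0.67235, abs=2e-4)


def test_conditional_establishment_requires_supercritical():
    scn = make_scenario(right=[0.105], right_iv=[1e-4], sigma_ben=0.075)
    with pytest.raises(ValueError, match="supercritical"):
        ig.conditional_establishment_supercritical(scn)


def test_survival_leading_order_tracks_exact():
    scn = make_scenario(right=[0.105], right_iv=[1e-4], sigma_ben=0.075)
    value, reliable = ig.survival_leading_order(scn)
    exact = ig.introgression_probability(scn)
    assert reliable
    assert value == pytest.approx(exact, rel=0.01)


def test_survival_leading_order_rejects_supercritical(worked_example):
    with pytest.raises(ValueError, match="subcritical"):
        ig.survival_leading_order(worked_example)
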