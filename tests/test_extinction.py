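import math

import pytest
from hypothesis import given, settings, strategies as st

import introgress as ig

from conftest import make_scenario


# ---------------------------------------------------------------------------
# Independent oracle: fixed-point iteration of the offspring-generating
# recursion.  Q = phi(Q) is iterated from Q == 0; monotone convergence to the
# minimal fixed point (the true extinction probabilities).


def fixed_point_table(scn, iters=200_000, tol=1e-14):
    arch = scn.architecture
    classes = list(arch.classes())
    Q = {cls: 0.0 for cls in classes}
    for _ in range(iters):
        delta = 0.0
        for (i, j, f) in classes:
            sigma = scn.sigma(i, j, f)
            r_tot = scn.r_total(i, j)
            targets = scn.recombination.targets(i, j)
            wf = 0.5**f
            # birth: offspring class extinction  x  parent continues (Q itself)
            born = 0.0
            for g in range(f + 1):
                binom = math.comb(f, g) * wf
                born += binom * (1.0 - r_tot) * Q[(i, j, g)]
                born += binom * sum(r * Q[(k, l, g)] for (k, l), r in targets.items())
            new = ((1.0 - sigma) + born * Q[(i, j, f)]) / (2.0 - sigma)
            delta = max(delta, abs(new - Q[(i, j, f)]))
            Q[(i, j, f)] = new
        if delta < tol:
            break
    return Q


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(right=[0.002], right_iv=[0.003], N=500, sigma_ben=0.012),
        dict(right=[0.005, 0.02, 0.065], rho=1e-4, sigma_ben=0.075),
        dict(left=[0.105], right=[0.005], rho=1e-4, sigma_ben=0.075),
        dict(unlinked=0.025, F=4, rho=0.0, sigma_ben=0.08),
        dict(right=[0.01, 0.075], left=[0.082], rho=1e-4, sigma_ben=0.08),
    ],
)
def test_recursion_matches_fixed_point_oracle(kwargs):
    scn = make_scenario(**kwargs)
    table = ig.extinction_table(scn)
    oracle = fixed_point_table(scn)
    for cls, q in oracle.items():
        assert table(*cls) == pytest.approx(q, abs=5e-11)


def test_base_case_is_sigma(clean_founder):
    assert ig.introgression_probability(clean_founder) == pytest.approx(0.08, abs=1e-12)


def test_closed_form_unlinked_matches_recursion():
    scn = make_scenario(unlinked=0.05, F=2, rho=0.0, sigma_ben=0.08)
    table = ig.extinction_table(scn)
    q0, q1, q2 = ig.closed_form_unlinked(0.08, 0.03, -0.02)
    assert table(0, 0, 0) == pytest.approx(q0, abs=1e-12)
    assert table(0, 0, 1) == pytest.approx(q1, abs=1e-12)
    assert table(0, 0, 2) == pytest.approx(q2, abs=1e-12)


def test_closed_form_single_linked_matches_recursion(worked_example):
    table = ig.extinction_table(worked_example)
    q = ig.closed_form_single_linked(0.012, 0.01, 0.003)
    assert table(0, 1, 0) == pytest.approx(q, abs=1e-14)
    assert table.survival(0, 1, 0) == pytest.approx(0.0104427, abs=5e-7)


@settings(max_examples=200, deadline=None)
@given(
    s00=st.floats(1e-3, 0.8),
    gap=st.floats(1e-4, 0.8),
    r01=st.floats(0.0, 0.49),
)
def test_single_linked_closed_form_is_a_root(s00, gap, r01):
    s01 = s00 - gap
    q = ig.closed_form_single_linked(s00, s01, r01)
    assert 0.0 <= q <= 1.0
    # root of (1-r) q^2 - (2 - s01 - r q00) q + (1 - s01) = 0
    q00 = 1.0 - s00
    resid = (1 - r01) * q * q - (2 - s01 - r01 * q00) * q + (1 - s01)
    assert abs(resid) < 1e-10


def test_taylor_single_linked_branches():
    exact = ig.closed_form_single_linked(0.012, 0.01, 1e-4)
    approx = ig.taylor_single_linked(0.012, 0.01, 1e-4)
    assert approx == pytest.approx(exact, abs=1e-5)
    exact_neg = ig.closed_form_single_linked(0.075, -0.02, 1e-4)
    approx_neg = ig.taylor_single_linked(0.075, -0.02, 1e-4)
    assert approx_neg == pytest.approx(exact_neg, abs=1e-5)
    with pytest.raises(ValueError):
        ig.taylor_single_linked(0.05, 0.0, 1e-4)


def test_survival_monotone_in_added_linked_alleles():
    # adding one more deleterious allele can only hurt
    prev = None
    for J in range(0, 5):
        scn = make_scenario(right=[0.01] * J, rho=1e-4, sigma_ben=0.08)
        p = ig.introgression_probability(scn)
        if prev is not None:
            assert p < prev
        prev = p


def test_survival_monotone_in_unlinked_alleles():
    prev = None
    for F in range(0, 6):
        scn = make_scenario(unlinked=0.02, F=F, rho=0.0, sigma_ben=0.08)
        p = ig.introgression_probability(scn)
        if prev is not None:
            assert p < prev
        prev = p


def test_tighter_linkage_hurts_more():
    probs = [
        ig.introgression_probability(
            make_scenario(right=[0.105], right_iv=[r], sigma_ben=0.075)
        )
        for r in (1e-5, 1e-4, 1e-3, 1e-2)
    ]
    assert probs == sorted(probs)


def test_relative_reduction_single_linked():
    base = make_scenario(sigma_ben=0.075, rho=0.0)
    with_allele = make_scenario(right=[0.105], right_iv=[1e-4], sigma_ben=0.075)
    out = ig.relative_reduction(with_allele, base)
    assert 0.9 < out["delta_P"] <= 1.0
    assert out["delta_P_small_r"] == pytest.approx(out["delta_P"], abs=0.01)


def test_relative_reduction_requires_same_baseline():
    a = make_scenario(sigma_ben=0.08, rho=0.0)
    b = make_scenario(sigma_ben=0.075, rho=0.0)
    with pytest.raises(ValueError, match="sigma"):
        ig.relative_reduction(a, b)


def test_subcritical_founder_survival_positive_via_rescue():
    # (0,1) is subcritical but its (0,0) recombinant rescues the process
    scn = make_scenario(right=[0.105], right_iv=[1e-4], sigma_ben=0.075)
    table = ig.extinction_table(scn)
    assert 0.0 < table.survival(0, 1, 0) < scn.sigma(0, 0, 0)
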