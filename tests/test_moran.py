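import math

import pytest

import introgress as ig
from introgress.moran import simulator_parameters

from conftest import make_scenario


def test_simulator_parameters_roundtrip():
    scn = make_scenario(
        left=[0.082], right=[0.01, 0.075], rho=1e-4, unlinked=0.01, F=2, sigma_ben=0.08
    )
    s_ben, lc, rc, uc, liv, riv = simulator_parameters(scn)
    assert s_ben == 0.08
    assert list(lc) == pytest.approx([0.082])
    assert list(rc) == pytest.approx([0.01, 0.075])
    assert uc == pytest.approx(0.01)
    assert list(liv) == pytest.approx([1e-4])
    assert list(riv) == pytest.approx([1e-4, 1e-4])


def test_simulator_rejects_non_additive_fitness():
    # margins imply sigma_(1,1) = 0.055; the table says 0.09 (epistasis)
    arch = ig.LinkedArchitecture(1, 1, 0)
    sigma = {
        (0, 0, 0): 0.075,
        (0, 1, 0): 0.07,
        (1, 0, 0): 0.06,
        (1, 1, 0): 0.09,
    }
    sel = ig.SelectionScheme(architecture=arch, sigma=sigma)
    rec = ig.build_uniform_recombination(1, 1, 1e-4)
    scn = ig.Scenario(N=1000, architecture=arch, selection=sel, recombination=rec)
    with pytest.raises(ValueError, match="additively consistent"):
        simulator_parameters(scn)


def test_simulator_rejects_source_dependent_recombination():
    rec = ig.build_matrix_recombination(
        0, 2, {((0, 2), (0, 1)): 1e-4, ((0, 2), (0, 0)): 1e-4, ((0, 1), (0, 0)): 5e-4}
    )
    sel = ig.build_additive_selection(0.075, right_effects=[0.005, 0.02])
    scn = ig.Scenario(
        N=1000, architecture=rec.architecture, selection=sel, recombination=rec
    )
    with pytest.raises(ValueError, match="interval-consistent"):
        simulator_parameters(scn)


def test_run_replicate_outcomes(clean_founder):
    from introgress.moran import run_replicate

    results = [run_replicate(clean_founder, seed=s, stop_fraction=0.05) for s in range(40)]
    kinds = {k for k, _ in results}
    assert kinds <= {"lost", "fixed"}
    for kind, cls in results:
        if kind == "fixed":
            assert cls == (0, 0)


def test_fixation_matches_exact_moran_chain():
    # r = 0, one class: fixation prob of one copy is s / (1 - (1-s)^N)
    # because the embedded chain's down/up ratio is exactly 1 - sigma.
    sigma, N = 0.08, 100
    scn = make_scenario(N=N, sigma_ben=sigma, rho=0.0)
    est = ig.estimate(scn, replicates=30_000, seed=11)
    exact = sigma / (1.0 - (1.0 - sigma) ** N)
    assert abs(est.introgression_prob - exact) < 3.0 * est.introgression_se
    assert est.fixation_dist == {(0, 0): 1.0}


def test_establishment_matches_gamblers_ruin():
    # P(reach stop_count before 0) = (1-g)/(1-g^n) with g = 1 - sigma,
    # independent of N
    sigma = 0.08
    expect = sigma / (1.0 - (1.0 - sigma) ** 50)
    for N, seed in ((100, 5), (2000, 6)):
        scn = make_scenario(N=N, sigma_ben=sigma, rho=0.0)
        est = ig.estimate(scn, replicates=20_000, seed=seed, stop_fraction=50 / N)
        assert abs(est.introgression_prob - expect) < 3.0 * est.introgression_se


def test_conditioned_estimate_counts_attempts():
    scn = make_scenario(N=200, sigma_ben=0.1, rho=0.0)
    est = ig.estimate(
        scn, replicates=200, seed=3, condition_on_success=True, stop_fraction=0.25
    )
    assert est.successes == 200
    assert est.attempts >= 200
    assert sum(est.fixation_dist.values()) == pytest.approx(1.0)


def test_seed_reproducibility():
    scn = make_scenario(N=300, sigma_ben=0.05, rho=0.0)
    a = ig.estimate(scn, replicates=2000, seed=7, stop_fraction=0.1)
    b = ig.estimate(scn, replicates=2000, seed=7, stop_fraction=0.1)
    c = ig.estimate(scn, replicates=2000, seed=8, stop_fraction=0.1)
    assert a.introgression_prob == b.introgression_prob
    assert a.introgression_prob != c.introgression_prob


def test_estimate_validation():
    scn = make_scenario(N=100, sigma_ben=0.05, rho=0.0)
    with pytest.raises(ValueError):
        ig.estimate(scn, replicates=0)
    with pytest.raises(ValueError):
        ig.estimate(scn, replicates=10, stop_fraction=1.5)


def test_moran_recombination_loses_allele():
    # with a strongly deleterious linked allele, successes are dominated by
    # the (0,0) recombinant
    scn = make_scenario(
        N=500, sigma_ben=0.075, right=[0.105], right_iv=[5e-3]
    )
    est = ig.estimate(
        scn, replicates=300, seed=9, condition_on_success=True, stop_fraction=0.2
    )
    assert est.fixation_dist.get((0, 0), 0.0) > 0.75
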