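import math

import pytest

import introgress as ig

from conftest import make_scenario


def worked_sweep(N=500):
    nu = ig.effective_initial_size(0.01, 0.003)
    return ig.SweepModel(
        N=N, sigma_est=0.01, sigma_targets=[0.012], r_targets=[0.003], nu_bar=nu
    )


def test_effective_initial_size():
    assert ig.effective_initial_size(0.01, 0.003) == pytest.approx(0.997 / 0.007)
    with pytest.raises(ValueError, match="supercritical"):
        ig.effective_initial_size(0.003, 0.01)


def test_sweep_model_validation():
    with pytest.raises(ValueError, match="exceed"):
        ig.SweepModel(N=500, sigma_est=0.01, sigma_targets=[0.005], r_targets=[0.001], nu_bar=10)
    with pytest.raises(ValueError, match="sigma_est"):
        ig.SweepModel(N=500, sigma_est=-0.01, sigma_targets=[], r_targets=[], nu_bar=10)


def test_logistic_frequency_path():
    m = worked_sweep()
    x0 = ig.logistic_frequency(0.0, m)
    assert x0 == pytest.approx(m.nu_bar / m.N)
    # monotone increasing, saturating at 1
    ts = [0, 100, 500, 2000, 10000]
    xs = [ig.logistic_frequency(t, m) for t in ts]
    assert xs == sorted(xs)
    assert xs[-1] > 0.999
    # half-way time: nu e^{st} = N - nu
    t_half = math.log((m.N - m.nu_bar) / m.nu_bar) / m.sigma_est
    assert ig.logistic_frequency(t_half, m) == pytest.approx(0.5, abs=1e-12)


def test_escape_establishment_endpoints():
    m = worked_sweep(N=10**9)  # keep x(0) ~ 0
    # empty background: standard establishment sigma_target
    assert ig.escape_establishment_probability(0.0, m) == pytest.approx(0.012, rel=1e-4)
    # fully swept background: relative advantage sigma_target - sigma_est
    late = ig.escape_establishment_probability(1e7, m)
    assert late == pytest.approx(0.002, rel=1e-4)
    # midpoint: harmonic-type interpolation
    t_half = math.log((m.N - m.nu_bar) / m.nu_bar) / m.sigma_est
    mid = ig.escape_establishment_probability(t_half, m)
    s, se = 0.012, 0.01
    assert mid == pytest.approx(s * (s - se) / ((s - se) * 0.5 + s * 0.5), rel=1e-6)


def test_retention_worked_example_value():
    m = worked_sweep()
    assert ig.retention_probability_single(m) == pytest.approx(0.795582, abs=1e-5)
    assert ig.retention_probability_single(m, use_nu_bar=False) == pytest.approx(
        0.524645, abs=1e-5
    )


def test_retention_limits():
    # r = 0: nothing can escape
    m0 = ig.SweepModel(N=500, sigma_est=0.01, sigma_targets=[0.012], r_targets=[0.0], nu_bar=143)
    assert ig.retention_probability_single(m0) == 1.0
    # nu_bar >= N/2 rejected
    mbad = ig.SweepModel(N=200, sigma_est=0.01, sigma_targets=[0.012], r_targets=[0.003], nu_bar=143)
    with pytest.raises(ValueError, match="N/2"):
        ig.retention_probability_single(mbad)
    # retention decreases with N (more escape opportunities)
    vals = [
        ig.retention_probability_single(worked_sweep(N=N), use_nu_bar=False)
        for N in (200, 500, 2000, 10000)
    ]
    assert vals == sorted(vals, reverse=True)


def test_nu_bar_and_limit_agree_for_large_N():
    # Eq. 40 -> Eq. 41 as nu_bar/N -> 0 (hold N*r fixed so the retention
    # probability itself stays O(1); the gap scales like nu_bar/N)
    nu = ig.effective_initial_size(0.01, 0.003)
    for N in (10**5, 10**6, 10**7):
        m = ig.SweepModel(
            N=N, sigma_est=0.01, sigma_targets=[0.012],
            r_targets=[1.5 / N], nu_bar=nu,
        )
        a = ig.retention_probability_single(m, use_nu_bar=True)
        b = ig.retention_probability_single(m, use_nu_bar=False)
        assert abs(a / b - 1.0) < 20.0 * nu / N


def test_retention_full_matches_single(worked_example):
    p_full = ig.retention_probability_full(worked_example, (0, 1), use_nu_bar=True)
    p_single = ig.retention_probability_single(worked_sweep())
    assert p_full == pytest.approx(p_single, abs=1e-12)


def test_retention_full_skips_unfit_targets():
    # (0,1) established; deeper target has negative fitness -> factor 1
    scn = make_scenario(right=[0.005, 0.095], rho=1e-4, sigma_ben=0.075)
    p = ig.retention_probability_full(scn, (0, 1), use_nu_bar=False)
    m = ig.SweepModel(
        N=scn.N, sigma_est=0.07, sigma_targets=[0.075], r_targets=[1e-4], nu_bar=1.0
    )
    assert p == pytest.approx(ig.retention_probability_single(m, use_nu_bar=False))


def test_retention_full_rejects_non_displacing_positive_target():
    # target fitter than 0 but below the established type: model undefined
    # built manually: established (0,1) fitness 0.08 > target (0,0) 0.075
    sigma = {(0, 0, 0): 0.075, (0, 1, 0): 0.08}
    arch = ig.LinkedArchitecture(0, 1, 0)
    sel = ig.SelectionScheme(architecture=arch, sigma=sigma)
    rec = ig.build_interval_recombination(right_intervals=[1e-4])
    scn = ig.Scenario(N=1000, architecture=arch, selection=sel, recombination=rec)
    with pytest.raises(ValueError, match="undefined"):
        ig.retention_probability_full(scn, (0, 1))


def test_det_phase_mc_matches_closed_form(worked_example):
    row = ig.det_phase_monte_carlo(worked_example, (0, 1), reps=4000, seed=7)
    closed = ig.retention_probability_single(worked_sweep())
    p = row.probabilities[(0, 1)]
    se = row.se[(0, 1)]
    assert abs(p - closed) < 3.0 * se
    assert row.method == "monte_carlo"
    assert sum(row.probabilities.values()) == pytest.approx(1.0)


def test_det_phase_mc_requires_supercritical():
    scn = make_scenario(right=[0.105], right_iv=[1e-4], sigma_ben=0.075)
    with pytest.raises(ValueError, match="supercritical"):
        ig.det_phase_monte_carlo(scn, (0, 1), reps=10, seed=0)


def test_det_phase_mc_no_escape_paths():
    scn = make_scenario(sigma_ben=0.08, rho=0.0)
    row = ig.det_phase_monte_carlo(scn, (0, 0), reps=100, seed=0)
    assert row.probabilities == {(0, 0): 1.0}
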