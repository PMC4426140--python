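"""Survival of the established haplotype through the selective sweep.

Once a carrier haplotype has established, its frequency path is modelled
deterministically (logistic growth seeded at the effective initial size
nu_bar = 1/p_est, which corrects for the conditioned fast early growth of a
surviving lineage).  During the sweep, recombination with wildtype keeps
producing fitter one-step recombinants; each such candidate is a
time-inhomogeneous birth-death lineage (birth rate 1, death rate
1 - sigma_candidate + mean population fitness) and establishes with a
time-dependent probability.  The established haplotype fixes iff no fitter
recombinant establishes first, which for a single escape target has the
closed-form power expression ``retention_probability_single``; competing
escape pathways are handled by the Monte-Carlo estimator
``det_phase_monte_carlo``, which evolves all established classes by
replicator dynamics and generates accepted escapes as a thinned
time-inhomogeneous Poisson stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import LinkedClass, Scenario
from .stochastic import is_supercritical, own_type_establishment

__all__ = [
    "SweepModel",
    "DetPhaseRow",
    "effective_initial_size",
    "logistic_frequency",
    "escape_establishment_probability",
    "retention_probability_single",
    "retention_probability_full",
    "det_phase_monte_carlo",
]


@dataclass(frozen=True)
class SweepModel:
    """Single-established-haplotype sweep with one-step escape targets.

    sigma_est: Malthusian fitness of the established (sweeping) haplotype.
    sigma_targets / r_targets: fitness of and per-birth recombination
    probability to each fitter one-step recombinant.
    nu_bar: effective initial number of copies of the established type.
    """

    N: int
    sigma_est: float
    sigma_targets: Sequence[float]
    r_targets: Sequence[float]
    nu_bar: float

    def __post_init__(self) -> None:
        if self.sigma_est <= 0:
            raise ValueError("sigma_est must be > 0")
        if len(self.sigma_targets) != len(self.r_targets):
            raise ValueError("sigma_targets and r_targets must align")
        for s in self.sigma_targets:
            if s <= self.sigma_est:
                raise ValueError(
                    f"escape target fitness {s} must exceed sigma_est "
                    f"{self.sigma_est} (else it cannot displace the sweep)"
                )
        if self.nu_bar < 1.0:
            raise ValueError("nu_bar must be >= 1")


@dataclass
class DetPhaseRow:
    """Empirical or analytic distribution over final classes for one sweep."""

    established: LinkedClass
    probabilities: Dict[LinkedClass, float]
    se: Dict[LinkedClass, float] = field(default_factory=dict)
    method: str = "closed_form"
    replicates: int = 0
    truncated: int = 0


def effective_initial_size(sigma_est: float, r_total: float) -> float:
    """nu_bar = 1/p_est = (1 - r) / (sigma - r); requires supercriticality."""
    p = own_type_establishment(sigma_est, r_total)
    if p <= 0.0:
        raise ValueError(
            "established type must be supercritical (sigma - r > 0) for a "
            "finite effective initial size"
        )
    return 1.0 / p


def logistic_frequency(t: float, sweep: SweepModel) -> float:
    """Frequency of the established type at time t >= 0 (logistic path)."""
    nu, N, s = sweep.nu_bar, sweep.N, sweep.sigma_est
    # decaying-exponential form stays finite for arbitrarily large t
    return 1.0 / (1.0 + ((N - nu) / nu) * math.exp(-s * t))


def escape_establishment_probability(T: float, sweep: SweepModel, target: int = 0) -> float:
    """Establishment probability of one escape recombinant born at time T.

    Closed form for a single sweeping background at logistic frequency
    x(T): sigma' (sigma' - sigma) / ((sigma' - sigma)(1 - x) + sigma' x)
    with sigma' the target's and sigma the established type's fitness.
    Interpolates from sigma' on an empty background to sigma' - sigma on a
    fully swept one.
    """
    s_t = sweep.sigma_targets[target]
    s_e = sweep.sigma_est
    x = logistic_frequency(T, sweep)
    return s_t * (s_t - s_e) / ((s_t - s_e) * (1.0 - x) + s_t * x)


def _retention_factor(
    N: int, sigma_target: float, sigma_est: float, r: float, nu_over_N: float
) -> float:
    """One closed-form retention factor (probability no escape through one
    pathway establishes during the sweep, frequency window
    [nu/N, 1 - nu/N])."""
    if r == 0.0:
        return 1.0
    base = (sigma_target - nu_over_N * sigma_est) / (
        sigma_target - sigma_est * (1.0 - nu_over_N)
    )
    expo = -N * r * sigma_target * (sigma_target - sigma_est) / (sigma_est**2)
    return base**expo


def retention_probability_single(sweep: SweepModel, use_nu_bar: bool = True) -> float:
    """Probability the established type fixes despite its escape pathways.

    With ``use_nu_bar`` the sweep starts at frequency nu_bar/N (valid for
    nu_bar < N/2); without it, the large-population limit nu_bar/N -> 0 is
    taken.  Accounting for the conditioned fast early growth (nu_bar)
    shortens the effective window and can change the answer appreciably in
    small populations.
    """
    nu_over_N = sweep.nu_bar / sweep.N if use_nu_bar else 0.0
    if use_nu_bar and sweep.nu_bar >= 0.5 * sweep.N:
        raise ValueError(
            f"nu_bar = {sweep.nu_bar} >= N/2 = {0.5 * sweep.N}: the sweep "
            "approximation requires nu_bar < 0.5 N"
        )
    p = 1.0
    for s_t, r in zip(sweep.sigma_targets, sweep.r_targets):
        p *= _retention_factor(sweep.N, s_t, sweep.sigma_est, r, nu_over_N)
    return p


def retention_probability_full(
    scenario: Scenario,
    established: LinkedClass,
    use_nu_bar: bool = False,
) -> float:
    """Probability that *all* linked alleles of ``established`` hitchhike.

    Product of one closed-form retention factor per one-step recombinant
    target of the established class.  Targets with non-positive fitness
    cannot establish and contribute factor 1; targets that are fitter than
    the established class contribute the sweep-escape factor; a target with
    positive fitness at or below the established class's fitness makes the
    displacement model inapplicable and is rejected.
    """
    I, J = established
    sigma_est = scenario.sigma(I, J, 0)
    r_tot = scenario.r_total(I, J)
    if sigma_est - r_tot <= 0.0:
        raise ValueError("established class must be supercritical")
    nu_over_N = 0.0
    if use_nu_bar:
        nu_over_N = effective_initial_size(sigma_est, r_tot) / scenario.N
        if nu_over_N >= 0.5:
            raise ValueError("nu_bar >= N/2: sweep approximation invalid")
    p = 1.0
    for (k, l), r in scenario.recombination.targets(I, J).items():
        s_t = scenario.sigma(k, l, 0)
        if s_t <= 0.0:
            continue
        if s_t <= sigma_est:
            raise ValueError(
                f"one-step target ({k},{l}) has positive fitness {s_t} not "
                f"exceeding the established type's {sigma_est}; the "
                "escape-displacement factor is undefined"
            )
        p *= _retention_factor(scenario.N, s_t, sigma_est, r, nu_over_N)
    return p


# ---------------------------------------------------------------------------
# Monte-Carlo deterministic phase with competing escape types


def _reachable(src: LinkedClass, tgt: LinkedClass) -> bool:
    """tgt reachable from src by (repeated) outside-in allele loss."""
    return tgt[0] <= src[0] and tgt[1] <= src[1] and tgt != src


def _epoch_paths(
    x0: np.ndarray, sig: np.ndarray, t: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Replicator dynamics with constant fitnesses has the explicit solution
    x_c(t) = x_c(0) e^{sigma_c t} / (x_wt(0) + sum_d x_d(0) e^{sigma_d t}).

    Returns (freqs[class, time], wildtype freq[time], mean fitness[time]).
    """
    x_wt0 = 1.0 - x0.sum()
    # subtract max exponent per time for stability
    expo = np.outer(sig, t)
    m = np.maximum(expo.max(axis=0), 0.0)
    num = x0[:, None] * np.exp(expo - m[None, :])
    den = x_wt0 * np.exp(-m) + num.sum(axis=0)
    x = num / den
    x_wt = x_wt0 * np.exp(-m) / den
    sbar = (sig[:, None] * x).sum(axis=0)
    return x, x_wt, sbar


def _establishment_path(
    sig_target: float, sbar: np.ndarray, t: np.ndarray, sbar_inf: float
) -> np.ndarray:
    """Establishment probability p(T) of a birth-death lineage born at grid
    times T, with birth rate 1 and death rate 1 - sig_target + sbar(t):
    p(T) = 1 / (1 + G(T)),  G(T) = int_T^inf d(t) exp(-int_T^t (sig-sbar)) dt,
    computed by backward recursion with an analytic constant-background tail.
    """
    if sig_target <= sbar_inf:
        return np.zeros_like(t)
    d = 1.0 - sig_target + sbar
    growth = sig_target - sbar
    n = len(t)
    G = np.empty(n)
    G[-1] = (1.0 - sig_target + sbar_inf) / (sig_target - sbar_inf)
    for i in range(n - 2, -1, -1):
        dt = t[i + 1] - t[i]
        g_mid = 0.5 * (growth[i] + growth[i + 1])
        decay = math.exp(-g_mid * dt)
        # trapezoid for the local source term
        G[i] = 0.5 * dt * (d[i] + d[i + 1] * decay) + decay * G[i + 1]
    return 1.0 / (1.0 + G)


def det_phase_monte_carlo(
    scenario: Scenario,
    established: LinkedClass,
    reps: int = 10_000,
    seed: int = 0,
    sample_nu: bool = False,
    grid_points: int = 400,
    max_time: float = float("inf"),
) -> DetPhaseRow:
    """Monte-Carlo distribution of the finally fixing class given that
    ``established`` established in the stochastic phase.

    Per replicate: all currently established classes follow deterministic
    replicator paths; each class c emits candidate recombinants of every
    fitter positive-fitness one-step target T as a Poisson stream with
    intensity N r^{c->T} x_c(t) x_wt(t), thinned by the time-dependent
    establishment probability of the candidate lineage; emission from c
    stops above frequency 1 - nu_bar_c/N, the validity window of the
    deterministic path.  Accepted candidates join the deterministic system
    at their own effective initial size and the replicate records the class
    that finally fixes (in replicator dynamics, the fittest established
    class).  Standard errors are binomial.
    """
    if not is_supercritical(scenario, *established):
        raise ValueError("established class must be supercritical")
    rng = np.random.default_rng(seed)
    N = scenario.N
    sigma_of = {cls: scenario.sigma(*cls, 0) for cls in scenario.architecture.linked_classes()}

    def nu_bar_for(cls: LinkedClass, p_est: Optional[float] = None) -> float:
        if p_est is not None and p_est > 0:
            nu = 1.0 / p_est
        else:
            nu = effective_initial_size(sigma_of[cls], scenario.r_total(*cls))
        return nu

    nu0 = nu_bar_for(established)
    if nu0 >= 0.5 * N:
        raise ValueError("nu_bar >= N/2 for the established class")

    counts: Dict[LinkedClass, int] = {}
    truncated = 0
    for _ in range(reps):
        if sample_nu:
            start_nu = max(1.0, rng.exponential(nu0))
        else:
            start_nu = nu0
        classes: List[LinkedClass] = [established]
        freqs: List[float] = [min(start_nu / N, 0.45)]
        windows: List[float] = [1.0 - min(start_nu, 0.45 * N) / N]
        t_elapsed = 0.0
        winner: Optional[LinkedClass] = None
        for _epoch in range(64):  # escapes strictly increase max fitness
            sig = np.array([sigma_of[c] for c in classes])
            x0 = np.array(freqs)
            s_max = sig.max()
            # grid until wildtype is essentially gone under the fittest class
            x_min = max(min(x0[sig == s_max]), 1e-12)
            span = (math.log(max(1.0 - x0.sum(), 1e-12) / x_min) + math.log(2.0 * N)) / max(s_max, 1e-12)
            span = min(span, max_time - t_elapsed)
            if span <= 0:
                truncated += 1
                winner = classes[int(np.argmax(sig))]
                break
            t = np.linspace(0.0, span, grid_points)
            x, x_wt, sbar = _epoch_paths(x0, sig, t)
            # candidate escape pathways: fitter than current fittest
            pathways = []  # (class index, target, r, p(t) path)
            for ci, c in enumerate(classes):
                for tgt, r in scenario.recombination.targets(*c).items():
                    if r <= 0.0 or tgt in classes:
                        continue
                    s_t = sigma_of[tgt]
                    if s_t <= s_max or s_t <= 0.0:
                        continue
                    p_path = _establishment_path(s_t, sbar, t, s_max)
                    pathways.append((ci, tgt, r, p_path))
            if not pathways:
                winner = classes[int(np.argmax(sig))]
                break
            lam = np.zeros((len(pathways), grid_points))
            for pi, (ci, _tgt, r, p_path) in enumerate(pathways):
                active = x[ci] < windows[ci]
                lam[pi] = N * r * x[ci] * x_wt * p_path * active
            lam_tot = lam.sum(axis=0)
            cum = np.concatenate(
                ([0.0], np.cumsum(0.5 * (lam_tot[1:] + lam_tot[:-1]) * np.diff(t)))
            )
            E = rng.exponential(1.0)
            if E >= cum[-1]:
                winner = classes[int(np.argmax(sig))]
                break
            k = int(np.searchsorted(cum, E))  # event inside [t_{k-1}, t_k]
            # linear inversion inside the step
            seg = cum[k] - cum[k - 1]
            frac = (E - cum[k - 1]) / seg if seg > 0 else 0.5
            t_star = t[k - 1] + frac * (t[k] - t[k - 1])
            # which pathway fired (weights at the event step)
            w = lam[:, k - 1] + frac * (lam[:, k] - lam[:, k - 1])
            if w.sum() <= 0:
                w = lam[:, k]
            pi = int(rng.choice(len(pathways), p=w / w.sum()))
            ci, tgt, r, p_path = pathways[pi]
            p_at = p_path[k - 1] + frac * (p_path[k] - p_path[k - 1])
            nu_new = nu_bar_for(tgt, p_est=p_at)
            # advance the deterministic system to t_star and add the escapee
            x_star, _, _ = _epoch_paths(x0, sig, np.array([t_star]))
            freqs = [float(v) for v in x_star[:, 0]]
            classes = list(classes)
            classes.append(tgt)
            freqs.append(min(nu_new / N, 0.45))
            windows.append(1.0 - min(nu_new, 0.45 * N) / N)
            t_elapsed += t_star
        else:  # pragma: no cover - epoch cap
            truncated += 1
            winner = classes[int(np.argmax([sigma_of[c] for c in classes]))]
        counts[winner] = counts.get(winner, 0) + 1

    probs = {cls: n / reps for cls, n in counts.items()}
    se = {cls: math.sqrt(p * (1.0 - p) / reps) for cls, p in probs.items()}
    return DetPhaseRow(
        established=established,
        probabilities=probs,
        se=se,
        method="monte_carlo",
        replicates=reps,
        truncated=truncated,
    )
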