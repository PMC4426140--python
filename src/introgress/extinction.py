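"""Extinction/introgression probabilities of the reducible branching process.

In the early phase of spread, carriers of the beneficial allele are rare and
evolve as a multitype branching process: a class-(i,j;f) individual dies at
rate 1 - sigma_(i,j;f) and gives birth at rate 1, the newborn inheriting the
linked block intact with probability 1 - r_(i,j) or a one-side-reduced block
(i,k), k<j or (k,j), k<i with probability r^(i,j)_target, and a Binomial(f,
1/2) number of the parent's unlinked alleles.  Because recombination with
wildtype can only *remove* alleles, the process is reducible and the
extinction probabilities solve a triangular system of scalar quadratics,
evaluated in order of increasing number of linked alleles and then unlinked
alleles.  The introgression probability of the beneficial allele is the
survival probability 1 - Q at the founder class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Tuple

from .config import FullClass, Scenario

__all__ = [
    "ExtinctionTable",
    "extinction_table",
    "introgression_probability",
    "closed_form_unlinked",
    "closed_form_single_linked",
    "taylor_single_linked",
    "relative_reduction",
]

#: default residual tolerance for the quadratic solve
RESIDUAL_TOL = 1e-12
#: slack allowed on the root bracket [0, 1]
BRACKET_SLACK = 1e-9


@dataclass(frozen=True)
class ExtinctionTable:
    """Extinction probability Q_(i,j;f) for every carrier class."""

    scenario: Scenario
    Q: Dict[FullClass, float]

    def __call__(self, i: int, j: int, f: int = 0) -> float:
        return self.Q[(i, j, f)]

    def survival(self, i: int, j: int, f: int = 0) -> float:
        return 1.0 - self.Q[(i, j, f)]


def _smaller_root(a: float, b: float, c: float) -> float:
    """Smaller root of a x^2 + b x + c = 0 (a > 0), cancellation-safe.

    In the weak-recombination regime the discriminant is only a tiny
    fraction of b^2, so the textbook formula loses precision; compute the
    well-conditioned root first and recover the other via Vieta.
    """
    disc = b * b - 4.0 * a * c
    if disc < 0.0:
        if disc > -1e-14 * max(b * b, 1.0):
            disc = 0.0
        else:
            raise ArithmeticError(
                f"negative discriminant {disc}: invalid scenario (no real "
                "extinction probability)"
            )
    sq = math.sqrt(disc)
    # b < 0 for every class here (it contains -(2 - sigma)), so -b + sq has
    # no cancellation; the smaller root follows from the product c/a.
    if b < 0.0:
        larger = (-b + sq) / (2.0 * a)
        return c / (a * larger)
    smaller = (-b - sq) / (2.0 * a)
    return smaller


def extinction_table(
    scenario: Scenario,
    residual_tol: float = RESIDUAL_TOL,
    bracket_slack: float = BRACKET_SLACK,
) -> ExtinctionTable:
    """Solve the full recursion for Q_(i,j;f) over all carrier classes.

    Classes are visited in order of increasing i + j, then increasing f, so
    each quadratic is scalar: all extinction probabilities on its right-hand
    side belong to classes with strictly fewer linked alleles or, at equal
    linked block, fewer unlinked alleles.  The smaller root is always the
    relevant one (the larger root is 1 for supercritical classes).
    """
    arch = scenario.architecture
    Q: Dict[FullClass, float] = {}
    order = sorted(arch.classes(), key=lambda cls: (cls[0] + cls[1], cls[2]))
    half = 0.5
    for (i, j, f) in order:
        sigma = scenario.sigma(i, j, f)
        r_tot = scenario.r_total(i, j)
        targets = scenario.recombination.targets(i, j)
        wf = half**f
        a = (1.0 - r_tot) * wf
        b = -(2.0 - sigma)
        for g in range(f + 1):
            binom = math.comb(f, g) * wf
            b += binom * sum(r * Q[(k, l, g)] for (k, l), r in targets.items())
            if g < f:
                b += binom * (1.0 - r_tot) * Q[(i, j, g)]
        c = 1.0 - sigma
        q = _smaller_root(a, b, c)
        if q < -bracket_slack or q > 1.0 + bracket_slack:
            raise ArithmeticError(
                f"extinction probability Q_({i},{j};{f}) = {q} outside [0, 1]"
            )
        q = min(max(q, 0.0), 1.0)
        resid = a * q * q + b * q + c
        scale = max(abs(a), abs(b), abs(c), 1.0)
        if abs(resid) > residual_tol * scale:
            raise ArithmeticError(
                f"quadratic residual {resid} for class ({i},{j};{f}) exceeds "
                f"tolerance {residual_tol}"
            )
        Q[(i, j, f)] = q
    return ExtinctionTable(scenario=scenario, Q=Q)


def introgression_probability(scenario: Scenario) -> float:
    """Probability the beneficial allele establishes, 1 - Q at the founder."""
    table = extinction_table(scenario)
    return table.survival(*scenario.founder)


# ---------------------------------------------------------------------------
# Closed forms for small architectures (cross-checks of the recursion)


def closed_form_unlinked(
    sigma0: float, sigma1: float | None = None, sigma2: float | None = None
) -> Tuple[float, ...]:
    """Extinction probabilities with 0, 1, 2 unlinked deleterious alleles.

    ``sigma_f`` is the fitness of the carrier haplotype with f unlinked
    alleles.  Returns as many Q values as fitnesses supplied:
    Q_0 = 1 - sigma_0 and the explicit radicals for Q_1, Q_2.
    """
    if sigma0 <= 0:
        raise ValueError("sigma0 must be > 0")
    q0 = 1.0 - sigma0
    out = [q0]
    if sigma1 is not None:
        h = 2.0 - sigma1 - 0.5 * q0
        disc = h * h - 2.0 * (1.0 - sigma1)
        if disc < 0:
            raise ArithmeticError("negative radical argument for Q_1")
        q1 = min(h - math.sqrt(disc), 1.0)
        out.append(q1)
        if sigma2 is not None:
            g = 0.25 * q0 + 0.5 * q1 - 2.0 + sigma2
            disc2 = g * g - (1.0 - sigma2)
            if disc2 < 0:
                raise ArithmeticError("negative radical argument for Q_2")
            q2 = min(4.0 - 2.0 * sigma2 - 0.5 * q0 - q1 - 2.0 * math.sqrt(disc2), 1.0)
            out.append(q2)
    return tuple(out)


def closed_form_single_linked(sigma00: float, sigma01: float, r01: float) -> float:
    """Extinction probability Q_(0,1) for one linked deleterious allele.

    Exact radical solution of the two-class recursion; equals the general
    recursion for I=0, J=1, F=0.  At r01 = 0.5 this coincides with the
    single-unlinked-allele Q_1 (single crossover makes a distance of one
    half equivalent to free recombination).
    """
    if sigma00 <= 0:
        raise ValueError("sigma00 must be > 0")
    if not 0.0 <= r01 < 1.0:
        raise ValueError("r01 must lie in [0, 1)")
    q00 = 1.0 - sigma00
    h = 2.0 - sigma01 - r01 * q00
    disc = h * h - 4.0 * (1.0 - sigma01) * (1.0 - r01)
    if disc < 0:
        raise ArithmeticError("negative discriminant for Q_(0,1)")
    # a subcritical root of exactly 1 can overshoot by roundoff
    return min((h - math.sqrt(disc)) / (2.0 * (1.0 - r01)), 1.0)


def taylor_single_linked(sigma00: float, sigma01: float, r01: float) -> float:
    """First-order-in-r approximation to Q_(0,1).

    Branches on the sign of sigma_(0,1); accuracy degrades as sigma_(0,1)
    approaches 0, where the expansion is singular.
    """
    if sigma01 == 0.0:
        raise ValueError("Taylor expansion is singular at sigma01 = 0")
    if sigma01 > 0.0:
        return (1.0 - sigma01) * (1.0 - (sigma00 - sigma01) / sigma01 * r01)
    return 1.0 + sigma00 / sigma01 * r01


def relative_reduction(
    scenario_with: Scenario, scenario_without: Scenario
) -> Dict[str, float]:
    """Relative drop in introgression probability due to extra alleles.

    ``delta_P = 1 - (1 - Q_with) / (1 - Q_without)``, with the two scenarios
    sharing the clean-background fitness sigma_(0,0).  Companion small-r and
    small-effect approximations are returned for diagnostics when the
    "with" scenario is the single-linked-allele case, together with the
    unlinked-compounding factor 1 - 2 S_del.
    """
    s0_with = scenario_with.sigma(0, 0, 0)
    s0_without = scenario_without.sigma(0, 0, 0)
    if abs(s0_with - s0_without) > 1e-12:
        raise ValueError("both scenarios must share sigma_(0,0)")
    p_without = introgression_probability(scenario_without)
    if p_without <= 0.0:
        raise ValueError("baseline introgression probability is 0")
    p_with = introgression_probability(scenario_with)
    delta = 1.0 - p_with / p_without
    out = {"delta_P": delta}
    arch = scenario_with.architecture
    if (arch.I, arch.J, arch.F) == (0, 1, 0):
        s00 = s0_with
        s01 = scenario_with.sigma(0, 1, 0)
        r01 = scenario_with.r_total(0, 1)
        s_del = s00 - s01
        if s01 > 0:
            out["delta_P_small_r"] = s_del / s00 * (1.0 - r01 / s01)
        elif s01 < 0:
            out["delta_P_small_r"] = 1.0 + r01 / s01
        out["delta_P_small_s"] = s_del / (r01 + s00 * (1.0 - r01))
    if (arch.I, arch.J) == (0, 0) and arch.F >= 1:
        # One unlinked allele of compound effect S_del reduces 1-Q by ~ 2 S_del.
        S_del = s0_with - scenario_with.sigma(0, 0, arch.F)
        out["unlinked_factor_approx"] = 1.0 - 2.0 * S_del
    return out
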