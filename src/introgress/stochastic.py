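"""Which haplotype establishes ("rescue type") given the process survives.

A class (i,j) is *supercritical* if its own-type lineage can grow,
sigma_(i,j) - r_(i,j) > 0; otherwise its own type is doomed and survival of
the introgression hinges on a recombinant lineage.  Conditioned on
survival, the distribution of the rescue type follows a recursion over the
reducible class graph: a supercritical founder almost surely rescues
itself, while a subcritical founder hands the process to each one-step
recombinant target with weight proportional to r_target * (1 - Q_target).
Unlinked alleles are shed in a few generations (each birth halves their
expected count), so rescue types are reported with f = 0; founders with
unlinked alleles additionally contribute the "lose one unlinked allele at
birth, keep the linked block" pathway.

The recursion implements the single-rescue approximation: exactly one
lineage escapes stochastic loss.  It is accurate for tight linkage and
clearly sub- or supercritical founders; the Moran simulator quantifies the
(small) error outside that regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Tuple

from .config import LinkedClass, Scenario
from .extinction import ExtinctionTable, extinction_table

__all__ = [
    "RescueDistribution",
    "own_type_establishment",
    "rescue_distribution",
    "conditional_establishment_supercritical",
    "survival_leading_order",
    "is_supercritical",
]


class NoSupercriticalHaplotype(ValueError):
    """No class with sigma - r > 0 is reachable: rescue is impossible."""


@dataclass(frozen=True)
class RescueDistribution:
    """P_(i,j): probability class (i,j) is the rescue type, given survival."""

    scenario: Scenario
    P: Dict[LinkedClass, float]

    def __call__(self, i: int, j: int) -> float:
        return self.P.get((i, j), 0.0)

    def support(self) -> Dict[LinkedClass, float]:
        return {cls: p for cls, p in self.P.items() if p > 0.0}


def is_supercritical(scenario: Scenario, i: int, j: int) -> bool:
    """Strict criterion sigma - r > 0; critical classes count as subcritical."""
    return scenario.sigma(i, j, 0) - scenario.r_total(i, j) > 0.0


def own_type_establishment(sigma: float, r_total: float) -> float:
    """Probability a single individual founds an infinite own-type lineage.

    For the linear birth-death process with death rate 1 - sigma and
    same-type birth rate 1 - r: 1 - q = (sigma - r) / (1 - r), clipped at 0
    for (sub)critical classes.
    """
    if r_total >= 1.0:
        raise ValueError("r_total must be < 1")
    return max(0.0, (sigma - r_total) / (1.0 - r_total))


def rescue_distribution(
    scenario: Scenario, table: ExtinctionTable | None = None
) -> RescueDistribution:
    """Distribution of the establishing haplotype, conditioned on survival.

    Raises :class:`NoSupercriticalHaplotype` when no class with
    sigma - r > 0 is reachable from the founder.
    """
    if table is None:
        table = extinction_table(scenario)
    arch = scenario.architecture
    memo: Dict[Tuple[int, int, int], Dict[LinkedClass, float]] = {}

    def dist(I: int, J: int, F: int) -> Dict[LinkedClass, float]:
        key = (I, J, F)
        if key in memo:
            return memo[key]
        if is_supercritical(scenario, I, J):
            out = {(I, J): 1.0}
            memo[key] = out
            return out
        targets = scenario.recombination.targets(I, J)
        r_tot = scenario.r_total(I, J)
        half_F = 0.5**F
        num: Dict[LinkedClass, float] = {}
        den = 0.0
        for l in range(F + 1):
            w = math.comb(F, l) * half_F
            for (k, m), r in targets.items():
                surv = table.survival(k, m, l)
                if surv <= 0.0:
                    continue
                weight = w * r * surv
                den += weight
                for cls, p in dist(k, m, l).items():
                    num[cls] = num.get(cls, 0.0) + weight * p
            if l < F:
                surv = table.survival(I, J, l)
                if surv > 0.0:
                    weight = w * (1.0 - r_tot) * surv
                    den += weight
                    for cls, p in dist(I, J, l).items():
                        num[cls] = num.get(cls, 0.0) + weight * p
        if den <= 0.0:
            memo[key] = {}
            return memo[key]
        out = {cls: v / den for cls, v in num.items()}
        memo[key] = out
        return out

    founder = scenario.founder
    P = dist(*founder)
    if not P:
        raise NoSupercriticalHaplotype(
            "no supercritical haplotype is reachable from the founder class "
            f"{founder}; the rescue distribution is undefined"
        )
    return RescueDistribution(scenario=scenario, P=P)


def conditional_establishment_supercritical(
    scenario: Scenario, table: ExtinctionTable | None = None
) -> float:
    """P that the founder itself establishes, given survival of the process.

    For a supercritical founder: (1 - q) / (1 - Q) with
    1 - q = (sigma - r) / (1 - r).  This refines the delta approximation of
    the rescue distribution and matters when r is not negligible against
    sigma^2 / sigma_(0,0).
    """
    if table is None:
        table = extinction_table(scenario)
    I, J, F = scenario.founder
    if not is_supercritical(scenario, I, J):
        raise ValueError("founder class is not supercritical")
    surv = table.survival(I, J, F)
    if surv <= 0.0:
        raise ValueError("founder survival probability is 0")
    p = own_type_establishment(scenario.sigma(I, J, 0), scenario.r_total(I, J)) / surv
    return min(p, 1.0)


def survival_leading_order(
    scenario: Scenario, table: ExtinctionTable | None = None
) -> Tuple[float, bool]:
    """Leading-order survival probability of a subcritical founder.

    Sum over one-step targets of r * (1 - Q_target), divided by
    r_total - sigma_founder (the expected number of recombination events of
    the founder's lineage per unit recombination probability).  Returns
    ``(value, reliable)`` where ``reliable`` is False when the linear term
    visibly overestimates (value substantially above the exact 1 - Q).
    """
    if table is None:
        table = extinction_table(scenario)
    I, J, F = scenario.founder
    sigma = scenario.sigma(I, J, F)
    r_tot = scenario.r_total(I, J)
    if sigma - r_tot >= 0.0:
        raise ValueError("founder class must be subcritical (sigma - r < 0)")
    num = sum(
        r * table.survival(k, l, F)
        for (k, l), r in scenario.recombination.targets(I, J).items()
    )
    value = num / (r_tot - sigma)
    exact = table.survival(I, J, F)
    reliable = value <= 1.25 * exact if exact > 0 else value == 0.0
    return value, reliable
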