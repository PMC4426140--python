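"""Concatenation of the stochastic and deterministic phases.

The probability that linked haplotype (i,j) ultimately fixes, conditioned on
successful introgression, is the rescue distribution composed with the
per-established-class deterministic-phase rows:

    P(type (i,j) fixes) = sum_{(k,l)} P_rescue[(k,l)] * P_det[(k,l) -> (i,j)]

Closed-form deterministic rows are used when the established class faces at
most one positive-fitness competitor (then the row is the two-outcome
retention/escape split); richer escape graphs fall back to the Monte-Carlo
deterministic phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

from .config import LinkedClass, Scenario
from .extinction import extinction_table, introgression_probability
from .stochastic import (
    conditional_establishment_supercritical,
    is_supercritical,
    rescue_distribution,
)
from .sweep import (
    DetPhaseRow,
    effective_initial_size,
    retention_probability_single,
    det_phase_monte_carlo,
    SweepModel,
)

__all__ = [
    "FixationDistribution",
    "fixation_distribution",
    "hitchhiking_probability",
    "reduction_factor",
    "quick_estimates",
]


@dataclass
class FixationDistribution:
    """Conditional and unconditional fixation probabilities per haplotype."""

    scenario: Scenario
    conditional: Dict[LinkedClass, float]
    introgression_prob: float
    method: Dict[LinkedClass, str] = field(default_factory=dict)
    se: Dict[LinkedClass, float] = field(default_factory=dict)

    @property
    def unconditional(self) -> Dict[LinkedClass, float]:
        return {c: p * self.introgression_prob for c, p in self.conditional.items()}


def _positive_fitness_classes(scenario: Scenario) -> set:
    return {
        (i, j)
        for (i, j) in scenario.architecture.linked_classes()
        if scenario.sigma(i, j, 0) > 0.0
    }


def _competitors(scenario: Scenario, established: LinkedClass) -> set:
    """Positive-fitness classes reachable from `established` by allele loss."""
    I, J = established
    return {
        (k, l)
        for (k, l) in _positive_fitness_classes(scenario)
        if k <= I and l <= J and (k, l) != established
    }


def _det_row(
    scenario: Scenario,
    established: LinkedClass,
    mc_reps: int,
    seed: int,
    use_nu_bar: bool,
    force_monte_carlo: bool = False,
) -> DetPhaseRow:
    comp = _competitors(scenario, established)
    one_step = {
        tgt
        for tgt, r in scenario.recombination.targets(*established).items()
        if r > 0.0 and scenario.sigma(*tgt, 0) > 0.0
    }
    if not force_monte_carlo and len(comp) == 0:
        return DetPhaseRow(established=established, probabilities={established: 1.0})
    if not force_monte_carlo and len(comp) == 1 and comp == one_step:
        (tgt,) = comp
        sigma_est = scenario.sigma(*established, 0)
        nu = effective_initial_size(sigma_est, scenario.r_total(*established))
        model = SweepModel(
            N=scenario.N,
            sigma_est=sigma_est,
            sigma_targets=[scenario.sigma(*tgt, 0)],
            r_targets=[scenario.r(established, tgt)],
            nu_bar=nu,
        )
        p = retention_probability_single(model, use_nu_bar=use_nu_bar)
        return DetPhaseRow(
            established=established, probabilities={established: p, tgt: 1.0 - p}
        )
    return det_phase_monte_carlo(scenario, established, reps=mc_reps, seed=seed)


def fixation_distribution(
    scenario: Scenario,
    mc_reps: int = 10_000,
    seed: int = 0,
    use_nu_bar: bool = True,
    force_monte_carlo: bool = False,
) -> FixationDistribution:
    """Distribution of the finally fixing linked haplotype.

    The rescue distribution gives the class that survives the stochastic
    phase; for a supercritical founder the refined conditional
    establishment probability (1-q)/(1-Q) replaces the delta weight, the
    complement flowing to the recombination-weighted rescue recursion of
    the founder's targets.  Each established class is then propagated
    through its deterministic-phase row.
    """
    table = extinction_table(scenario)
    I, J, F = scenario.founder
    rescue = dict(rescue_distribution(scenario, table).P)
    if is_supercritical(scenario, I, J):
        # refine the delta approximation at the founder
        p_self = conditional_establishment_supercritical(scenario, table)
        rest = 1.0 - p_self
        if rest > 1e-12:
            # distribute the complement over the founder's rescue targets
            sub = {}
            den = 0.0
            for tgt, r in scenario.recombination.targets(I, J).items():
                s = table.survival(*tgt, F)
                if s <= 0 or r <= 0:
                    continue
                den += r * s
                sub[tgt] = r * s
            if den > 0:
                rescue = {(I, J): p_self}
                for tgt, w in sub.items():
                    inner = _founder_restricted_rescue(scenario, table, tgt)
                    for cls, p in inner.items():
                        rescue[cls] = rescue.get(cls, 0.0) + rest * (w / den) * p
            else:
                rescue = {(I, J): 1.0}
        else:
            rescue = {(I, J): 1.0}

    conditional: Dict[LinkedClass, float] = {}
    method: Dict[LinkedClass, str] = {}
    se_acc: Dict[LinkedClass, float] = {}
    for est, w in rescue.items():
        if w <= 0.0:
            continue
        row = _det_row(scenario, est, mc_reps, seed, use_nu_bar, force_monte_carlo)
        for cls, p in row.probabilities.items():
            conditional[cls] = conditional.get(cls, 0.0) + w * p
            if row.method == "monte_carlo":
                method[cls] = "monte_carlo"
                se_acc[cls] = math.hypot(se_acc.get(cls, 0.0), w * row.se.get(cls, 0.0))
            else:
                method.setdefault(cls, "closed_form")
    return FixationDistribution(
        scenario=scenario,
        conditional=conditional,
        introgression_prob=table.survival(I, J, F),
        method=method,
        se=se_acc,
    )


def _founder_restricted_rescue(scenario, table, founder_linked):
    """Rescue distribution of the sub-process started at a linked class."""
    from .stochastic import is_supercritical as _sc

    memo: Dict[LinkedClass, Dict[LinkedClass, float]] = {}

    def dist(cls: LinkedClass) -> Dict[LinkedClass, float]:
        if cls in memo:
            return memo[cls]
        if _sc(scenario, *cls):
            memo[cls] = {cls: 1.0}
            return memo[cls]
        num: Dict[LinkedClass, float] = {}
        den = 0.0
        for tgt, r in scenario.recombination.targets(*cls).items():
            s = table.survival(*tgt, 0)
            if s <= 0 or r <= 0:
                continue
            den += r * s
            for c2, p in dist(tgt).items():
                num[c2] = num.get(c2, 0.0) + r * s * p
        memo[cls] = {c: v / den for c, v in num.items()} if den > 0 else {}
        return memo[cls]

    return dist(founder_linked)


def hitchhiking_probability(
    scenario: Scenario,
    target: LinkedClass,
    mc_reps: int = 10_000,
    seed: int = 0,
    use_nu_bar: bool = True,
) -> float:
    """Conditional probability that haplotype ``target`` fixes.

    Read off from the fixation distribution; for the single-hitchhiker
    scenario this is the product of the conditional establishment
    probability and the deterministic-phase retention probability.
    """
    dist = fixation_distribution(scenario, mc_reps=mc_reps, seed=seed, use_nu_bar=use_nu_bar)
    return dist.conditional.get(tuple(target), 0.0)


def reduction_factor(scenario: Scenario) -> float:
    """Factor c by which a second, subcritical linked allele on the same
    side reduces the hitchhiking probability of the first:

        c = 1 / (1 + r^(0,2)_(0,1) sigma_(0,1) / (r^(0,2)_(0,0) sigma_(0,0)))

    Valid for I=0, J=2 with (0,1) supercritical and (0,2) subcritical.
    """
    arch = scenario.architecture
    if (arch.I, arch.J) != (0, 2):
        raise ValueError("reduction_factor requires I=0, J=2")
    if is_supercritical(scenario, 0, 2):
        raise ValueError("the outer allele must make the founder subcritical")
    if not is_supercritical(scenario, 0, 1):
        raise ValueError("class (0,1) must be supercritical")
    r_keep = scenario.r((0, 2), (0, 1))
    r_lose = scenario.r((0, 2), (0, 0))
    if r_lose <= 0:
        raise ValueError("r^(0,2)_(0,0) must be positive")
    ratio = r_keep * scenario.sigma(0, 1, 0) / (r_lose * scenario.sigma(0, 0, 0))
    return 1.0 / (1.0 + ratio)


def quick_estimates(scenario: Scenario) -> Dict[str, Dict[str, object]]:
    """Back-of-envelope closed forms with their validity assumptions.

    Each entry reports ``value`` (or None), ``applicable`` and the
    assumption under which the formula holds; inapplicable formulas are
    returned with ``applicable = False`` rather than raised.
    """
    arch = scenario.architecture
    out: Dict[str, Dict[str, object]] = {}

    def entry(name, value, applicable, assumption):
        out[name] = {"value": value, "applicable": applicable, "assumption": assumption}

    # Two alleles one side: rescue weight of (0,1) (tight linkage).
    if (arch.I, arch.J) == (0, 2) and not is_supercritical(scenario, 0, 2):
        s00, s01 = scenario.sigma(0, 0, 0), scenario.sigma(0, 1, 0)
        r0 = scenario.r((0, 2), (0, 0))
        r1 = scenario.r((0, 2), (0, 1))
        if s01 > 0:
            v = r1 * s01 / (r0 * s00 + r1 * s01)
            entry("rescue_weight_01", v, True,
                  "tight linkage, (0,2) subcritical, 1-Q ~ sigma")
            entry("reduction_factor", reduction_factor(scenario), True,
                  "same assumptions; c = 1/(1 + r1 s01 / (r0 s00))")
            entry("second_allele_relevant_below_r", r0 * s00 / s01, True,
                  "second allele matters for r^(0,2)_(0,1) below this scale")
    # Flanking configuration: weight of (0,1) among the two single-allele types.
    if (arch.I, arch.J) == (1, 1) and not is_supercritical(scenario, 1, 1):
        s01, s10 = scenario.sigma(0, 1, 0), scenario.sigma(1, 0, 0)
        r01 = scenario.r((1, 1), (0, 1))
        r10 = scenario.r((1, 1), (1, 0))
        if s01 > 0 and s10 > 0:
            v = r01 * s01 / (r10 * s10 + r01 * s01)
            entry("flanking_rescue_weight_01", v, True,
                  "both single-allele types supercritical, (1,1) subcritical")
    # One-sided chain: rescue weights over the supercritical prefix.
    if arch.I == 0 and arch.J >= 1 and not is_supercritical(scenario, 0, arch.J):
        j_sup = [k for k in range(arch.J) if is_supercritical(scenario, 0, k)]
        if j_sup:
            jmax = max(j_sup)
            den = sum(
                scenario.r((0, arch.J), (0, l)) * scenario.sigma(0, l, 0)
                for l in range(jmax + 1)
            )
            if den > 0:
                weights = {
                    (0, k): scenario.r((0, arch.J), (0, k)) * scenario.sigma(0, k, 0) / den
                    for k in range(jmax + 1)
                }
                entry("chain_rescue_weights", weights, True,
                      "tight linkage, alleles beyond the supercritical prefix "
                      "do not enter")
    if not out:
        entry("none", None, False, "no quick formula applies to this architecture")
    return out
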