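"""Exact stochastic simulation of the full Moran model with recombination.

The population holds N haploid individuals.  At each event two parents are
drawn uniformly with replacement; with at most one crossover (interval m of
the linked block with probability chi_m) the two recombination products are
formed and the transmitted one picked with probability 1/2, or, without
crossover, the linked block of a uniformly chosen parent is copied; every
unlinked locus is inherited from a uniformly chosen parent independently.
The offspring replaces a victim drawn with probability proportional to
1 - sigma (fitness-weighted death); all three draws are with replacement, so
a parent may also be the victim.  Event times are not tracked: only
absorption probabilities matter.

Genotypes are full bit sets over the linked loci (carriers need not stay
contiguous once hybrids recombine with each other) plus independent
presence bits for the unlinked loci, so the simulator makes none of the
branching-process approximations - it is the ground-truth oracle for the
analytic modules.  A per-capita bookkeeping identity ties the two together:
a rare carrier produces a same-type offspring at rate 1 - sum(chi) and the
interval-m recombinant at rate chi_m, exactly the branching-process birth
rates when chi_m is identified with the analytic recombination
probabilities; parameters are therefore shared verbatim.

Events in which all three drawn individuals are wildtype leave the state
unchanged; the event loop samples directly from the conditional law of
state-changing events, which makes the cost per replicate proportional to
the integrated number of non-wildtype individuals rather than to absolute
time.

Requirements: an interval-consistent recombination scheme (uniform or
intervals mode) and an additively consistent fitness table - a physical
crossover position, and the fitness of the non-contiguous genotypes the
full model can create, cannot be defined otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from numba import njit

from .config import Scenario

__all__ = ["SimEstimate", "estimate", "run_replicate", "simulator_parameters"]

_LOST, _FIXED = 0, 1
_MAXC = 4096  # genotype classes present at once (realised counts are tens)


@dataclass
class SimEstimate:
    """Monte-Carlo estimates from the Moran simulator."""

    introgression_prob: float
    introgression_se: float
    fixation_dist: Dict[Tuple[int, int], float]
    fixation_se: Dict[Tuple[int, int], float]
    attempts: int
    successes: int
    seed: int
    stop_fraction: Optional[float] = None


# ---------------------------------------------------------------------------
# Scenario -> primitive parameter extraction


def simulator_parameters(scenario: Scenario):
    """Derive per-allele costs and crossover interval probabilities.

    Raises ValueError for fitness tables that are not additively closed or
    recombination schemes whose target probabilities depend on the source
    class (no physical crossover position exists then).
    """
    arch = scenario.architecture
    I, J, F = arch.I, arch.J, arch.F
    s_ben = scenario.sigma(0, 0, 0)
    left_costs = np.array(
        [scenario.sigma(m, 0, 0) - scenario.sigma(m + 1, 0, 0) for m in range(I)]
    )
    right_costs = np.array(
        [scenario.sigma(0, m, 0) - scenario.sigma(0, m + 1, 0) for m in range(J)]
    )
    unlinked_cost = 0.0
    if F > 0:
        unlinked_cost = scenario.sigma(0, 0, 0) - scenario.sigma(0, 0, 1)
    for i, j, f in arch.classes():
        add = s_ben - left_costs[:i].sum() - right_costs[:j].sum() - f * unlinked_cost
        if abs(add - scenario.sigma(i, j, f)) > 1e-9:
            raise ValueError(
                "the simulator needs an additively consistent fitness table "
                f"(class ({i},{j};{f}): table {scenario.sigma(i, j, f)}, "
                f"additive closure {add})"
            )
    left_iv = np.zeros(I)
    right_iv = np.zeros(J)
    for k in range(I):
        left_iv[k] = scenario.r((I, 0), (k, 0)) if I else 0.0
    for k in range(J):
        right_iv[k] = scenario.r((0, J), (0, k)) if J else 0.0
    for (i, j) in arch.linked_classes():
        for (k, l), r in scenario.recombination.targets(i, j).items():
            expect = left_iv[k] if l == j else right_iv[l]
            if abs(r - expect) > 1e-12:
                raise ValueError(
                    "the simulator needs interval-consistent recombination "
                    f"probabilities (source ({i},{j}) -> ({k},{l}) has r={r}, "
                    f"interval value {expect})"
                )
    return s_ben, left_costs, right_costs, unlinked_cost, left_iv, right_iv


# ---------------------------------------------------------------------------
# numba core


@njit(cache=False, inline="always")
def _next64(state):
    state = (state + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = state
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    return state, z


@njit(cache=False, inline="always")
def _u01(state):
    state, z = _next64(state)
    return state, (z >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=False)
def _fitness(key, I, J, F, s_ben, left_costs, right_costs, unlinked_cost):
    s = s_ben if key & 1 else 0.0
    for m in range(I):
        if key & (1 << (1 + m)):
            s -= left_costs[m]
    for m in range(J):
        if key & (1 << (1 + I + m)):
            s -= right_costs[m]
    if unlinked_cost != 0.0:
        for m in range(F):
            if key & (1 << (1 + I + J + m)):
                s -= unlinked_cost
    return s


@njit(cache=False)
def _replicate(
    state,
    N,
    I,
    J,
    F,
    s_ben,
    left_costs,
    right_costs,
    unlinked_cost,
    civ,
    stop_count,
):
    """One introgression attempt.  Returns (code, linked_key, state).

    code 0: beneficial allele lost.  code 1: success - either the carrier
    count reached stop_count (establishment mode, linked_key = most common
    carrier's linked genotype) or, with stop_count > N, the population is
    monomorphic for one beneficial-carrying linked haplotype.
    """
    linked_mask = (1 << (1 + I + J)) - 1
    unlinked_mask = ((1 << F) - 1) << (1 + I + J) if F > 0 else 0
    n_iv = I + J
    r_sum = civ[n_iv - 1] if n_iv > 0 else 0.0

    keys = np.zeros(_MAXC, dtype=np.int64)
    counts = np.zeros(_MAXC, dtype=np.int64)
    sig = np.zeros(_MAXC, dtype=np.float64)
    # index 0 is permanently the wildtype class
    founder = 1
    for m in range(I):
        founder |= 1 << (1 + m)
    for m in range(J):
        founder |= 1 << (1 + I + m)
    for m in range(F):
        founder |= 1 << (1 + I + J + m)
    keys[0] = 0
    counts[0] = N - 1
    sig[0] = 0.0
    keys[1] = founder
    counts[1] = 1
    sig[1] = _fitness(founder, I, J, F, s_ben, left_costs, right_costs, unlinked_cost)
    nc = 2
    n_ben = 1

    while True:
        if n_ben == 0:
            return 0, np.int64(0), state
        if n_ben >= stop_count:
            best = np.int64(-1)
            bestn = np.int64(-1)
            for c in range(nc):
                if (keys[c] & 1) and counts[c] > bestn:
                    bestn = counts[c]
                    best = keys[c]
            return 1, best & linked_mask, state
        if n_ben == N and stop_count > N:
            mono = True
            ref = keys[0] & linked_mask if counts[0] > 0 else np.int64(-1)
            for c in range(nc):
                if counts[c] == 0:
                    continue
                lk = keys[c] & linked_mask
                if ref == np.int64(-1):
                    ref = lk
                elif lk != ref:
                    mono = False
                    break
            if mono:
                return 1, ref, state

        # --- event, conditioned on involving a non-wildtype individual ----
        W = 0.0
        for c in range(nc):
            W += counts[c] * (1.0 - sig[c])
        pW = counts[0] / N  # parent draw is wildtype
        vW = counts[0] / W  # victim draw is wildtype
        p_noop = pW * pW * vW
        state, u = _u01(state)
        u *= 1.0 - p_noop
        # enumerate combos (p1, p2, v) in {W, H}; skip (W, W, W)
        p1H = False
        p2H = False
        vH = False
        acc = 0.0
        done = False
        for b1 in range(2):
            q1 = pW if b1 == 0 else 1.0 - pW
            for b2 in range(2):
                q2 = pW if b2 == 0 else 1.0 - pW
                for b3 in range(2):
                    if b1 == 0 and b2 == 0 and b3 == 0:
                        continue
                    q3 = vW if b3 == 0 else 1.0 - vW
                    acc += q1 * q2 * q3
                    if u < acc:
                        p1H = b1 == 1
                        p2H = b2 == 1
                        vH = b3 == 1
                        done = True
                        break
                if done:
                    break
            if done:
                break

        # sample the class of each role
        nonwt = N - counts[0]
        g1 = np.int64(0)
        if p1H:
            state, u = _u01(state)
            target = u * nonwt
            acc2 = 0.0
            for c in range(1, nc):
                acc2 += counts[c]
                if target < acc2:
                    g1 = keys[c]
                    break
        g2 = np.int64(0)
        if p2H:
            state, u = _u01(state)
            target = u * nonwt
            acc2 = 0.0
            for c in range(1, nc):
                acc2 += counts[c]
                if target < acc2:
                    g2 = keys[c]
                    break
        vidx = 0
        if vH:
            WH = W - counts[0]
            state, u = _u01(state)
            target = u * WH
            acc2 = 0.0
            for c in range(1, nc):
                acc2 += counts[c] * (1.0 - sig[c])
                if target < acc2:
                    vidx = c
                    break

        # --- offspring genotype ------------------------------------------
        state, u = _u01(state)
        off_linked = np.int64(0)
        if n_iv > 0 and u < r_sum:
            m = 0
            while civ[m] <= u:
                m += 1
            if m < I:  # crossover in left interval m
                outer = ((1 << (I - m)) - 1) << (1 + m)
            else:  # right interval m - I
                k = m - I
                outer = ((1 << (J - k)) - 1) << (1 + I + k)
            inner = linked_mask & ~outer
            prod1 = (g1 & outer) | (g2 & inner)
            prod2 = (g2 & outer) | (g1 & inner)
            state, u = _u01(state)
            off_linked = prod1 if u < 0.5 else prod2
        else:
            state, u = _u01(state)
            off_linked = (g1 if u < 0.5 else g2) & linked_mask
        off = off_linked
        if F > 0:
            state, z = _next64(state)
            M = np.int64(z & np.uint64(0x7FFFFFFFFFFFFFFF)) & unlinked_mask
            off |= (g1 & M) | (g2 & ~M & unlinked_mask)

        # --- replace victim ----------------------------------------------
        if keys[vidx] & 1:
            n_ben -= 1
        counts[vidx] -= 1
        if counts[vidx] == 0 and vidx > 0:
            nc -= 1
            keys[vidx] = keys[nc]
            counts[vidx] = counts[nc]
            sig[vidx] = sig[nc]
        oidx = -1
        for c in range(nc):
            if keys[c] == off:
                oidx = c
                break
        if oidx < 0:
            oidx = nc
            keys[oidx] = off
            counts[oidx] = 0
            sig[oidx] = _fitness(
                off, I, J, F, s_ben, left_costs, right_costs, unlinked_cost
            )
            nc += 1
        counts[oidx] += 1
        if off & 1:
            n_ben += 1


@njit(cache=False)
def _run_batch(
    base_seed,
    n_target,
    condition_on_success,
    max_attempts,
    N,
    I,
    J,
    F,
    s_ben,
    left_costs,
    right_costs,
    unlinked_cost,
    civ,
    stop_count,
):
    """Run replicates; returns (codes, linked_keys, attempts).

    Without conditioning, exactly n_target attempts are made.  With
    conditioning, attempts continue until n_target successes (or
    max_attempts), and only successes are recorded.
    """
    codes = np.empty(n_target, dtype=np.int64)
    linked = np.empty(n_target, dtype=np.int64)
    got = 0
    attempts = 0
    while got < n_target and attempts < max_attempts:
        # independent stream per attempt: avalanche the (seed, attempt) pair
        # so the splitmix orbit offsets between attempts are pseudo-random
        # (a raw additive offset would alias the generator's own increment)
        raw = np.uint64(base_seed) * np.uint64(0xD1342543DE82EF95) + np.uint64(
            attempts
        ) * np.uint64(0xA0761D6478BD642F) + np.uint64(1)
        raw, z = _next64(raw)
        state, z = _next64(z)
        code, lk, state = _replicate(
            state, N, I, J, F, s_ben, left_costs, right_costs, unlinked_cost, civ,
            stop_count,
        )
        attempts += 1
        if condition_on_success:
            if code == 1:
                codes[got] = code
                linked[got] = lk
                got += 1
        else:
            codes[got] = code
            linked[got] = lk
            got += 1
    return codes[:got], linked[:got], attempts


# ---------------------------------------------------------------------------
# Python wrappers


def run_replicate(scenario: Scenario, seed: int = 0, stop_fraction: Optional[float] = None):
    """Simulate one introgression attempt.

    Returns ``("lost", None)`` or ``("fixed", (i, j))`` where (i, j) are the
    left/right linked-allele counts of the winning carrier haplotype.
    """
    params = simulator_parameters(scenario)
    s_ben, lc, rc, uc, liv, riv = params
    arch = scenario.architecture
    civ = np.cumsum(np.concatenate([liv, riv])) if arch.I + arch.J else np.zeros(0)
    stop = _stop_count(scenario.N, stop_fraction)
    code, lk, _ = _replicate(
        np.uint64(seed * 2 + 1),
        scenario.N,
        arch.I,
        arch.J,
        arch.F,
        s_ben,
        lc,
        rc,
        uc,
        civ,
        stop,
    )
    if code == 0:
        return "lost", None
    return "fixed", _linked_class(int(lk), arch.I, arch.J)


def _stop_count(N: int, stop_fraction: Optional[float]) -> int:
    if stop_fraction is None:
        return N + 1  # run to monomorphism
    if not 0.0 < stop_fraction <= 1.0:
        raise ValueError("stop_fraction must lie in (0, 1]")
    return max(2, int(math.ceil(stop_fraction * N)))


def _linked_class(linked_key: int, I: int, J: int) -> Tuple[int, int]:
    left = (linked_key >> 1) & ((1 << I) - 1) if I else 0
    right = (linked_key >> (1 + I)) & ((1 << J) - 1) if J else 0
    return (int(left).bit_count(), int(right).bit_count())


def estimate(
    scenario: Scenario,
    replicates: int,
    seed: int = 0,
    condition_on_success: bool = False,
    stop_fraction: Optional[float] = None,
    max_attempts: Optional[int] = None,
) -> SimEstimate:
    """Monte-Carlo introgression and fixation-distribution estimates.

    Without conditioning, ``replicates`` introgression attempts are run and
    the success fraction estimates the introgression probability.  With
    ``condition_on_success``, attempts continue until ``replicates``
    successes; the per-haplotype fractions then estimate the conditional
    fixation distribution.  ``stop_fraction`` declares success as soon as
    carriers reach that population fraction (establishment estimand);
    leaving it unset runs every replicate to monomorphism of the
    beneficial-carrying linked haplotype (fixation estimand, ignoring
    unlinked loci).  Identical seeds give identical estimates.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    params = simulator_parameters(scenario)
    s_ben, lc, rc, uc, liv, riv = params
    arch = scenario.architecture
    civ = np.cumsum(np.concatenate([liv, riv])) if arch.I + arch.J else np.zeros(0)
    stop = _stop_count(scenario.N, stop_fraction)
    if max_attempts is None:
        max_attempts = replicates if not condition_on_success else 200_000_000
    if condition_on_success:
        p_guess = max(introgression_guess(scenario), 1e-12)
        if replicates * 1.0 / max(p_guess, 1e-300) > max_attempts:
            warnings.warn("expected attempts exceed max_attempts; estimate may truncate")
        if p_guess * max_attempts < 10:
            warnings.warn("fewer than 10 successes expected; estimates will be noisy")
    codes, linked, attempts = _run_batch(
        np.uint64(seed & 0x7FFFFFFF),
        replicates,
        condition_on_success,
        max_attempts,
        scenario.N,
        arch.I,
        arch.J,
        arch.F,
        s_ben,
        lc,
        rc,
        uc,
        civ,
        stop,
    )
    n = len(codes)
    succ = int((codes == 1).sum())
    if condition_on_success:
        p_intro = succ / attempts
        se_intro = math.sqrt(p_intro * (1 - p_intro) / attempts)
    else:
        p_intro = succ / n if n else float("nan")
        se_intro = math.sqrt(p_intro * (1 - p_intro) / n) if n else float("nan")
    fix: Dict[Tuple[int, int], int] = {}
    for code, lk in zip(codes, linked):
        if code == 1:
            cls = _linked_class(int(lk), arch.I, arch.J)
            fix[cls] = fix.get(cls, 0) + 1
    dist = {c: k / succ for c, k in fix.items()} if succ else {}
    dist_se = {c: math.sqrt(p * (1 - p) / succ) for c, p in dist.items()} if succ else {}
    return SimEstimate(
        introgression_prob=p_intro,
        introgression_se=se_intro,
        fixation_dist=dist,
        fixation_se=dist_se,
        attempts=int(attempts),
        successes=succ,
        seed=seed,
        stop_fraction=stop_fraction,
    )


def introgression_guess(scenario: Scenario) -> float:
    """Cheap analytic guess used only to warn about hopeless conditioning."""
    from .extinction import introgression_probability

    try:
        return introgression_probability(scenario)
    except Exception:
        return 0.01
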