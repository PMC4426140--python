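"""Scenario definition: haplotype space, fitness scheme, recombination scheme.

A scenario describes a single hybridization event: one hybrid individual
enters a resident population of ``N`` haploids, carrying one beneficial
allele, ``I`` linked deleterious alleles to its left, ``J`` to its right,
and ``F`` unlinked deleterious alleles.  Carrier haplotype classes are
indexed ``(i, j; f)`` with ``0 <= i <= I``, ``0 <= j <= J``,
``0 <= f <= F``; linked alleles are numbered outward from the beneficial
locus (allele 1 is nearest), and class ``(i, j)`` carries the *i* nearest
left and the *j* nearest right alleles.  Contiguity of the linked block is
guaranteed within the branching approximation because recombination with
wildtype can only truncate the block from the outside.

Fitness is Malthusian, measured relative to wildtype (= 0): an individual
of class ``(i, j; f)`` dies at rate ``1 - sigma_(i,j;f)`` and gives birth
at rate 1, so ``sigma`` must stay below 1.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Optional, Tuple

__all__ = [
    "LinkedArchitecture",
    "SelectionScheme",
    "RecombinationScheme",
    "Scenario",
    "build_additive_selection",
    "build_uniform_recombination",
    "build_interval_recombination",
    "build_matrix_recombination",
    "scenario_to_dict",
    "scenario_from_dict",
]

LinkedClass = Tuple[int, int]
FullClass = Tuple[int, int, int]


@dataclass(frozen=True)
class LinkedArchitecture:
    """Counts of deleterious loci around the beneficial locus.

    ``I``/``J``: linked loci left/right of the beneficial allele;
    ``F``: unlinked loci.  All unlinked alleles share one effect size.
    """

    I: int
    J: int
    F: int = 0

    def __post_init__(self) -> None:
        for name in ("I", "J", "F"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    def linked_classes(self) -> Iterator[LinkedClass]:
        for i in range(self.I + 1):
            for j in range(self.J + 1):
                yield (i, j)

    def classes(self) -> Iterator[FullClass]:
        for i, j in self.linked_classes():
            for f in range(self.F + 1):
                yield (i, j, f)


@dataclass(frozen=True)
class SelectionScheme:
    """Malthusian fitness sigma_(i,j;f) of every carrier haplotype class.

    Wildtype fitness is identically 0 and is not stored.  The map must
    cover every class of the architecture, every value must be < 1 (death
    rates are 1 - sigma), and the clean-background carrier (0,0;0) must be
    advantageous (sigma > 0).
    """

    architecture: LinkedArchitecture
    sigma: Mapping[FullClass, float]

    def __post_init__(self) -> None:
        arch = self.architecture
        table = dict(self.sigma)
        for cls in arch.classes():
            if cls not in table:
                raise ValueError(f"selection scheme missing class {cls}")
            s = table[cls]
            if not math.isfinite(s) or s >= 1.0:
                raise ValueError(
                    f"sigma{cls} = {s} invalid: Malthusian fitness must be finite "
                    "and < 1 (death rate 1 - sigma must stay positive)"
                )
        if table[(0, 0, 0)] <= 0.0:
            raise ValueError(
                "sigma_(0,0;0) must be > 0: the beneficial allele has to be "
                "advantageous on a clean background"
            )
        object.__setattr__(self, "sigma", table)

    def __call__(self, i: int, j: int, f: int = 0) -> float:
        return self.sigma[(i, j, f)]

    @property
    def s_ben(self) -> float:
        """Fitness of the beneficial allele on a clean background."""
        return self.sigma[(0, 0, 0)]


@dataclass(frozen=True)
class RecombinationScheme:
    """Per-birth recombination probabilities between linked classes.

    ``r_target[(i, j)][(k, l)]`` is the probability that a birth of an
    ``(i, j)`` parent (mated with wildtype) produces the recombinant
    ``(k, l)``; only single-side reductions (``(i, k)`` with ``k < j`` or
    ``(k, j)`` with ``k < i``) are allowed, reflecting the single-crossover
    assumption.  ``r_total(i, j)`` is the sum over all targets.
    """

    architecture: LinkedArchitecture
    r_target: Mapping[LinkedClass, Mapping[LinkedClass, float]]

    def __post_init__(self) -> None:
        arch = self.architecture
        table: Dict[LinkedClass, Dict[LinkedClass, float]] = {}
        for src in arch.linked_classes():
            entries = dict(self.r_target.get(src, {}))
            total = 0.0
            for tgt, r in entries.items():
                if not _is_single_side_reduction(src, tgt):
                    raise ValueError(
                        f"recombination {src} -> {tgt} is not a single-side "
                        "reduction (single crossover only)"
                    )
                if r < 0.0 or not math.isfinite(r):
                    raise ValueError(f"r{src}->{tgt} = {r} must be >= 0")
                total += r
            if total >= 1.0:
                raise ValueError(
                    f"total recombination probability r_{src} = {total} must be < 1"
                )
            table[src] = entries
        object.__setattr__(self, "r_target", table)

    def targets(self, i: int, j: int) -> Dict[LinkedClass, float]:
        return dict(self.r_target[(i, j)])

    def r(self, src: LinkedClass, tgt: LinkedClass) -> float:
        return self.r_target[src].get(tgt, 0.0)

    def r_total(self, i: int, j: int) -> float:
        return sum(self.r_target[(i, j)].values())


def _is_single_side_reduction(src: LinkedClass, tgt: LinkedClass) -> bool:
    i, j = src
    k, l = tgt
    return (k == i and 0 <= l < j) or (l == j and 0 <= k < i)


@dataclass(frozen=True)
class Scenario:
    """A complete model instance shared by analytics and the simulator."""

    N: int
    architecture: LinkedArchitecture
    selection: SelectionScheme
    recombination: RecombinationScheme
    # Round-trippable description of how the scenario was built (optional).
    meta: Dict[str, object] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"population size N must be >= 2, got {self.N}")
        if self.selection.architecture != self.architecture:
            raise ValueError("selection scheme architecture does not match scenario")
        if self.recombination.architecture != self.architecture:
            raise ValueError("recombination scheme architecture does not match scenario")

    # Convenience accessors used throughout the analytic modules -----------
    def sigma(self, i: int, j: int, f: int = 0) -> float:
        return self.selection(i, j, f)

    def r(self, src: LinkedClass, tgt: LinkedClass) -> float:
        return self.recombination.r(src, tgt)

    def r_total(self, i: int, j: int) -> float:
        return self.recombination.r_total(i, j)

    @property
    def founder(self) -> FullClass:
        a = self.architecture
        return (a.I, a.J, a.F)


# ---------------------------------------------------------------------------
# Builders


def build_additive_selection(
    sigma_ben: float,
    left_effects: Optional[List[float]] = None,
    right_effects: Optional[List[float]] = None,
    unlinked_effect: float = 0.0,
    F: int = 0,
) -> SelectionScheme:
    """Additive fitness: sigma_(i,j;f) = sigma_ben - sum of allele costs.

    Each effect is the positive fitness cost of one deleterious allele;
    ``left_effects[m-1]``/``right_effects[m-1]`` is the cost of the m-th
    allele counted outward from the beneficial locus.  All unlinked alleles
    share ``unlinked_effect``.
    """
    left = list(left_effects or [])
    right = list(right_effects or [])
    if any(e < 0 for e in left + right) or unlinked_effect < 0:
        raise ValueError("allele effects are fitness costs and must be >= 0")
    if sigma_ben >= 1.0:
        raise ValueError("sigma_ben must be < 1")
    arch = LinkedArchitecture(I=len(left), J=len(right), F=F)
    sigma: Dict[FullClass, float] = {}
    for i, j, f in arch.classes():
        s = sigma_ben - sum(left[:i]) - sum(right[:j]) - f * unlinked_effect
        if s >= 1.0:
            raise ValueError(f"sigma_({i},{j};{f}) = {s} >= 1")
        sigma[(i, j, f)] = s
    return SelectionScheme(architecture=arch, sigma=sigma)


def build_uniform_recombination(I: int, J: int, rho: float, F: int = 0) -> RecombinationScheme:
    """Every source->target probability equals ``rho``: r_(i,j) = (i+j) rho."""
    if rho < 0:
        raise ValueError("rho must be >= 0")
    arch = LinkedArchitecture(I=I, J=J, F=F)
    if (I + J) * rho >= 1.0:
        raise ValueError(f"(I+J)*rho = {(I + J) * rho} must be < 1")
    table: Dict[LinkedClass, Dict[LinkedClass, float]] = {}
    for i, j in arch.linked_classes():
        entries: Dict[LinkedClass, float] = {}
        for k in range(i):
            entries[(k, j)] = rho
        for k in range(j):
            entries[(i, k)] = rho
        table[(i, j)] = entries
    return RecombinationScheme(architecture=arch, r_target=table)


def build_interval_recombination(
    left_intervals: Optional[List[float]] = None,
    right_intervals: Optional[List[float]] = None,
    F: int = 0,
) -> RecombinationScheme:
    """Recombination from per-interval crossover probabilities.

    ``left_intervals[k]``/``right_intervals[k]`` is the per-birth
    probability of a single crossover in the interval between linked locus
    k and locus k+1 on that side (index 0 = interval adjacent to the
    beneficial locus).  The resulting target probabilities are independent
    of the source class: r^(i,j)_(i,k) = right_intervals[k] for k < j.
    """
    left = list(left_intervals or [])
    right = list(right_intervals or [])
    if any(p < 0 for p in left + right):
        raise ValueError("interval probabilities must be >= 0")
    if sum(left) + sum(right) >= 1.0:
        raise ValueError("sum of crossover interval probabilities must be < 1")
    arch = LinkedArchitecture(I=len(left), J=len(right), F=F)
    table: Dict[LinkedClass, Dict[LinkedClass, float]] = {}
    for i, j in arch.linked_classes():
        entries: Dict[LinkedClass, float] = {}
        for k in range(i):
            entries[(k, j)] = left[k]
        for k in range(j):
            entries[(i, k)] = right[k]
        table[(i, j)] = entries
    return RecombinationScheme(architecture=arch, r_target=table)


def build_matrix_recombination(
    I: int,
    J: int,
    entries: Mapping[Tuple[LinkedClass, LinkedClass], float],
    F: int = 0,
) -> RecombinationScheme:
    """Explicit source->target probabilities, possibly source-dependent.

    This is the most general scheme the analytic modules accept.  The Moran
    simulator requires interval-consistent schemes (uniform or intervals)
    because a physical crossover position cannot depend on the genotype.
    """
    arch = LinkedArchitecture(I=I, J=J, F=F)
    table: Dict[LinkedClass, Dict[LinkedClass, float]] = {
        (i, j): {} for i, j in arch.linked_classes()
    }
    for (src, tgt), r in entries.items():
        table[tuple(src)][tuple(tgt)] = float(r)
    return RecombinationScheme(architecture=arch, r_target=table)


# ---------------------------------------------------------------------------
# Serialization (JSON-compatible dict; see io.load_scenario for files)


def scenario_to_dict(scenario: Scenario) -> Dict[str, object]:
    arch = scenario.architecture
    d: Dict[str, object] = {
        "N": scenario.N,
        "I": arch.I,
        "J": arch.J,
        "F": arch.F,
        "sigma_table": {
            f"{i},{j},{f}": scenario.selection(i, j, f) for i, j, f in arch.classes()
        },
        "recombination": {
            "mode": "matrix",
            "entries": {
                f"{i},{j}->{k},{l}": r
                for (i, j) in arch.linked_classes()
                for (k, l), r in scenario.recombination.targets(i, j).items()
            },
        },
    }
    if scenario.meta:
        d["meta"] = dict(scenario.meta)
    return d


def _parse_selection(cfg: Mapping[str, object], arch: LinkedArchitecture) -> SelectionScheme:
    table = cfg.get("sigma_table")
    builder_keys = {"sigma_ben", "left_effects", "right_effects", "unlinked_effect"}
    if table is not None:
        # Explicit table wins when both are given.
        sigma = {
            tuple(int(x) for x in key.split(",")): float(v) for key, v in table.items()
        }
        # Allow "i,j" shorthand for f = 0.
        sigma = {(k + (0,) * (3 - len(k))): v for k, v in sigma.items()}
        return SelectionScheme(architecture=arch, sigma=sigma)
    if not builder_keys & set(cfg):
        raise ValueError("config must provide sigma_table or additive effects")
    if isinstance(cfg.get("unlinked_effects"), list):
        raise ValueError(
            "per-allele unlinked effects are not supported; unlinked alleles "
            "are exchangeable with one common 'unlinked_effect'"
        )
    scheme = build_additive_selection(
        sigma_ben=float(cfg["sigma_ben"]),
        left_effects=[float(x) for x in cfg.get("left_effects", [])],
        right_effects=[float(x) for x in cfg.get("right_effects", [])],
        unlinked_effect=float(cfg.get("unlinked_effect", 0.0)),
        F=arch.F,
    )
    if scheme.architecture != arch:
        raise ValueError(
            f"effect lists imply architecture I={scheme.architecture.I}, "
            f"J={scheme.architecture.J} but config says I={arch.I}, J={arch.J}"
        )
    return scheme


def _parse_recombination(cfg: Mapping[str, object], arch: LinkedArchitecture) -> RecombinationScheme:
    mode = cfg.get("mode", "uniform")
    if mode == "uniform":
        return build_uniform_recombination(arch.I, arch.J, float(cfg["rho"]), F=arch.F)
    if mode == "intervals":
        return build_interval_recombination(
            left_intervals=[float(x) for x in cfg.get("left_intervals", [])],
            right_intervals=[float(x) for x in cfg.get("right_intervals", [])],
            F=arch.F,
        )
    if mode == "matrix":
        entries = {}
        for key, r in cfg["entries"].items():
            src_s, tgt_s = key.split("->")
            src = tuple(int(x) for x in src_s.split(","))
            tgt = tuple(int(x) for x in tgt_s.split(","))
            entries[(src, tgt)] = float(r)
        return build_matrix_recombination(arch.I, arch.J, entries, F=arch.F)
    raise ValueError(f"unknown recombination mode {mode!r}")


def scenario_from_dict(cfg: Mapping[str, object]) -> Scenario:
    try:
        arch = LinkedArchitecture(
            I=int(cfg.get("I", len(cfg.get("left_effects", [])))),
            J=int(cfg.get("J", len(cfg.get("right_effects", [])))),
            F=int(cfg.get("F", 0)),
        )
        selection = _parse_selection(cfg, arch)
        recombination = _parse_recombination(cfg.get("recombination", {"mode": "uniform", "rho": 0.0}), arch)
        return Scenario(
            N=int(cfg["N"]),
            architecture=arch,
            selection=selection,
            recombination=recombination,
            meta=dict(cfg.get("meta", {})),
        )
    except KeyError as exc:
        raise ValueError(f"config is missing required key {exc}") from exc


def scenario_to_json(scenario: Scenario, **kwargs) -> str:
    return json.dumps(scenario_to_dict(scenario), indent=2, **kwargs)
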