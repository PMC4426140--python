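"""Named scenario fixtures for the worked examples and figure settings.

Each fixture is a complete :class:`~introgress.config.Scenario` plus, where
the original setting sweeps a parameter, a grid describing that sweep.  They
exist so every analysis in the documentation and test-suite starts from one
canonical parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

from .config import (
    Scenario,
    build_additive_selection,
    build_interval_recombination,
    build_uniform_recombination,
)

__all__ = ["ScenarioFixture", "FIXTURES", "get_fixture", "list_fixtures"]


@dataclass
class ScenarioFixture:
    name: str
    description: str
    scenario: Scenario
    sweep: Optional[Dict[str, List[float]]] = None


def _scn(N, selection, recombination, **meta) -> Scenario:
    return Scenario(
        N=N,
        architecture=selection.architecture,
        selection=selection,
        recombination=recombination,
        meta=meta,
    )


def _fig2(S_del: float = 0.1, F_max: int = 10) -> ScenarioFixture:
    # F unlinked alleles of total effect S_del; scenario stored at F = 4.
    F = 4
    sel = build_additive_selection(0.08, unlinked_effect=S_del / F, F=F)
    rec = build_uniform_recombination(0, 0, 0.0, F=F)
    return ScenarioFixture(
        name="fig2",
        description=(
            "introgression probability versus the number of unlinked "
            "deleterious alleles at constant total effect; sigma_0 = 0.08"
        ),
        scenario=_scn(10_000, sel, rec, fixture="fig2", S_del=S_del),
        sweep={"F": list(range(0, F_max + 1))},
    )


def _fig3(unlinked_effect: float, name: str) -> ScenarioFixture:
    F = 4
    sel = build_additive_selection(
        0.075,
        right_effects=[0.005, 0.02, 0.065],  # sigma 0.075/0.07/0.05/-0.015
        unlinked_effect=unlinked_effect,
        F=F,
    )
    rec = build_uniform_recombination(0, 3, 1e-4, F=F)
    return ScenarioFixture(
        name=name,
        description=(
            "hitchhiking probability versus the number of unlinked alleles "
            f"(per-allele unlinked cost {unlinked_effect}); I=0, J=3"
        ),
        scenario=_scn(10_000, sel, rec, fixture=name),
        sweep={"F": list(range(0, 5))},
    )


def _fig4(panel: str) -> ScenarioFixture:
    N = 10_000 if panel in "ac" else 500
    sel = build_additive_selection(0.012, right_effects=[0.002])
    rec = build_interval_recombination(right_intervals=[0.003 if N == 500 else 0.001])
    grid = [1e-5, 3e-5, 1e-4, 3e-4, 1e-3, 3e-3, 1e-2]
    return ScenarioFixture(
        name=f"fig4{panel}",
        description=(
            "single linked deleterious allele, sigma_(0,0)=0.012, "
            f"sigma_(0,1)=0.01, N={N}; sweep over r_(0,1)"
        ),
        scenario=_scn(N, sel, rec, fixture=f"fig4{panel}"),
        sweep={"r01": grid},
    )


def _fig5(panel: str) -> ScenarioFixture:
    sigma02 = -0.03 if panel in "ac" else 0.065
    sel = build_additive_selection(0.075, right_effects=[0.005, 0.07 - sigma02])
    rec = build_interval_recombination(right_intervals=[1e-4, 1e-4])
    return ScenarioFixture(
        name=f"fig5{panel}",
        description=(
            "two linked deleterious alleles on the same side; "
            f"sigma_(0,2)={sigma02}; sweep over r^(0,2)_(0,1)"
        ),
        scenario=_scn(10_000, sel, rec, fixture=f"fig5{panel}"),
        sweep={"r12": [1e-5, 3e-5, 1e-4, 3e-4, 1e-3, 3e-3, 1e-2]},
    )


def _fig6(panel: str) -> ScenarioFixture:
    if panel in "ac":
        s01, s10 = 0.07, -0.025  # implies sigma_(1,1) = -0.03 additively
    else:
        s01, s10 = 0.04, 0.03  # implies sigma_(1,1) = -0.005
    sel = build_additive_selection(
        0.075, left_effects=[0.075 - s10], right_effects=[0.075 - s01]
    )
    rec = build_interval_recombination(left_intervals=[1e-4], right_intervals=[1e-4])
    return ScenarioFixture(
        name=f"fig6{panel}",
        description=(
            "beneficial allele flanked by two deleterious alleles; "
            f"sigma_(0,1)={s01}, sigma_(1,0)={s10}; sweep over r^(1,1)_(0,1)"
        ),
        scenario=_scn(10_000, sel, rec, fixture=f"fig6{panel}"),
        sweep={"r01": [1e-5, 3e-5, 1e-4, 3e-4, 1e-3, 3e-3, 1e-2]},
    )


def _fig7(sigma02: float = -0.03) -> ScenarioFixture:
    sel = build_additive_selection(0.075, right_effects=[0.005, 0.07 - sigma02])
    rec = build_interval_recombination(right_intervals=[1e-4, 1e-4])
    return ScenarioFixture(
        name="fig7",
        description=(
            "two linked alleles one side at equal distances r=1e-4; "
            "sweep over sigma_(0,2)"
        ),
        scenario=_scn(10_000, sel, rec, fixture="fig7"),
        sweep={"sigma02": [-0.1, -0.05, -0.03, -0.01, 0.0, 0.02, 0.04, 0.06, 0.069]},
    )


def _fig8(sigma10: float = -0.03) -> ScenarioFixture:
    sel = build_additive_selection(
        0.075, left_effects=[0.075 - sigma10], right_effects=[0.005]
    )
    rec = build_interval_recombination(left_intervals=[1e-4], right_intervals=[1e-4])
    return ScenarioFixture(
        name="fig8",
        description=(
            "flanking configuration at equal distances r=1e-4; sweep over "
            "sigma_(1,0)"
        ),
        scenario=_scn(10_000, sel, rec, fixture="fig8"),
        sweep={"sigma10": [-0.1, -0.05, -0.03, -0.01, 0.0, 0.02, 0.04, 0.06, 0.069]},
    )


def fig9_scenario(I: int, J: int = 2, N: int = 10_000) -> Scenario:
    """Many linked alleles: only (0,0) and (0,1) have positive fitness.

    Fitness anatomy: sigma_(0,0)=0.08, sigma_(0,1)=0.07, sigma_(0,2)=-0.005,
    sigma_(1,0)=-0.002; every further allele costs 0.01; every pairwise
    recombination probability is 1e-4.
    """
    right = [0.01, 0.075] + [0.01] * max(0, J - 2)
    right = right[:J]
    left = [0.082] + [0.01] * max(0, I - 1)
    left = left[:I]
    sel = build_additive_selection(0.08, left_effects=left, right_effects=right)
    rec = build_uniform_recombination(I, J, 1e-4)
    return _scn(N, sel, rec, fixture="fig9", I=I, J=J)


def _fig9() -> ScenarioFixture:
    return ScenarioFixture(
        name="fig9",
        description=(
            "hitchhiking of a single slightly deleterious allele surrounded "
            "by I left / J=2 right alleles of which only (0,0),(0,1) are fit; "
            "sweep over I"
        ),
        scenario=fig9_scenario(I=1, J=2),
        sweep={"I": list(range(0, 11))},
    )


def _worked_example() -> ScenarioFixture:
    sel = build_additive_selection(0.012, right_effects=[0.002])
    rec = build_interval_recombination(right_intervals=[0.003])
    return ScenarioFixture(
        name="worked_example_10_2",
        description=(
            "single-hitchhiker point example: N=500, sigma_(0,0)=0.012, "
            "sigma_(0,1)=0.01, r_(0,1)=0.003"
        ),
        scenario=_scn(500, sel, rec, fixture="worked_example_10_2"),
    )


_BUILDERS: Dict[str, Callable[[], ScenarioFixture]] = {
    "fig2": _fig2,
    "fig3a": lambda: _fig3(0.01, "fig3a"),
    "fig3b": lambda: _fig3(0.05, "fig3b"),
    "fig4a": lambda: _fig4("a"),
    "fig4b": lambda: _fig4("b"),
    "fig4c": lambda: _fig4("c"),
    "fig4d": lambda: _fig4("d"),
    "fig5a": lambda: _fig5("a"),
    "fig5b": lambda: _fig5("b"),
    "fig5c": lambda: _fig5("c"),
    "fig5d": lambda: _fig5("d"),
    "fig6a": lambda: _fig6("a"),
    "fig6b": lambda: _fig6("b"),
    "fig6c": lambda: _fig6("c"),
    "fig6d": lambda: _fig6("d"),
    "fig7": _fig7,
    "fig8": _fig8,
    "fig9": _fig9,
    "worked_example_10_2": _worked_example,
}

FIXTURES = tuple(sorted(_BUILDERS))


def list_fixtures() -> Tuple[str, ...]:
    return FIXTURES


def get_fixture(name: str) -> ScenarioFixture:
    try:
        return _BUILDERS[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available fixtures: {', '.join(FIXTURES)}"
        ) from None
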