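import pytest

import introgress as ig


@pytest.fixture(scope="session")
def worked_example():
    """N=500, sigma_(0,0)=0.012, sigma_(0,1)=0.01, r_(0,1)=0.003."""
    return ig.get_fixture("worked_example_10_2").scenario


@pytest.fixture(scope="session")
def clean_founder():
    """No deleterious alleles, sigma = 0.08, N = 10000."""
    sel = ig.build_additive_selection(0.08)
    rec = ig.build_uniform_recombination(0, 0, 0.0)
    return ig.Scenario(
        N=10_000, architecture=sel.architecture, selection=sel, recombination=rec
    )


def make_scenario(
    N=10_000,
    sigma_ben=0.08,
    left=(),
    right=(),
    unlinked=0.0,
    F=0,
    rho=None,
    left_iv=None,
    right_iv=None,
):
    sel = ig.build_additive_selection(
        sigma_ben, left_effects=list(left), right_effects=list(right),
        unlinked_effect=unlinked, F=F,
    )
    if rho is not None:
        rec = ig.build_uniform_recombination(len(left), len(right), rho, F=F)
    else:
        rec = ig.build_interval_recombination(
            left_intervals=list(left_iv or [0.0] * len(left)),
            right_intervals=list(right_iv or [0.0] * len(right)),
            F=F,
        )
    return ig.Scenario(
        N=N, architecture=sel.architecture, selection=sel, recombination=rec
    )
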