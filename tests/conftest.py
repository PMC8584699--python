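import pytest

from comgapfill import build_community
from comgapfill.fixtures import FixtureSpec, make_linear_fixture, random_fixture
from comgapfill.fva import reduce_community
from comgapfill.gapfill import formulate, solve


@pytest.fixture(scope="session")
def disjoint_fixture():
    """Two members, one planted gap each, no exchange: minimal repair 2."""
    return make_linear_fixture(
        FixtureSpec(
            n_members=2, chain_length=4, n_db_total=6,
            planted_gaps={0: [2], 1: [1]}, seed=1,
        )
    )


@pytest.fixture(scope="session")
def crossfed_fixture():
    """Member 1's gap is bypassed by a metabolite member 0 secretes: repair 1."""
    return make_linear_fixture(
        FixtureSpec(
            n_members=2, chain_length=4, n_db_total=4,
            planted_gaps={0: [2], 1: [1]}, planted_exchanges=[(0, 1)], seed=2,
        )
    )


@pytest.fixture(scope="session")
def intact_fixture():
    """Single member without gaps: nothing to repair."""
    return make_linear_fixture(
        FixtureSpec(n_members=1, chain_length=3, n_db_total=2, seed=3)
    )


def pipeline(fx, *, prune=True):
    """Build, optionally FVA-prune, and solve a fixture community."""
    cm = build_community(fx.members(), fx.database, fx.medium)
    if prune:
        cm, _ = reduce_community(cm)
    problem = formulate(cm)
    return cm, problem, solve(problem)


@pytest.fixture(scope="session")
def solved_random_batch():
    """(fixture, pruned community, problem, solution) for a seeded batch."""
    out = []
    for seed in range(20):
        fx = random_fixture(seed)
        cm, problem, sol = pipeline(fx)
        out.append((fx, cm, problem, sol))
    return out
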