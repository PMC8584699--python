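"""The community gap-filling MILP: optimality, constraints, enumeration."""

import numpy as np
import pytest

from comgapfill import (
    ModelError,
    ReactionDatabase,
    build_community,
    community_system,
)
from comgapfill.fixtures import FixtureSpec, make_linear_fixture, random_fixture
from comgapfill.fva import reduce_community
from comgapfill.gapfill import (
    Support,
    apply_and_verify,
    enumerate_alternatives,
    formulate,
    solve,
)
from tests.conftest import pipeline


def test_binary_count_is_members_times_candidates(disjoint_fixture):
    fx = disjoint_fixture
    cm = build_community(fx.members(), fx.database, fx.medium)
    problem = formulate(cm)
    # no candidate duplicates a model reaction here, so every member gets
    # one binary per database reaction
    assert problem.n_binaries == 2 * len(fx.database)


def test_growth_floor_must_be_positive(disjoint_fixture):
    fx = disjoint_fixture
    cm = build_community(fx.members(), fx.database, fx.medium)
    with pytest.raises(ModelError, match="positive"):
        formulate(cm, growth_floors={"org0": 0.0, "org1": 0.1})


def test_weighted_requires_abundances(disjoint_fixture):
    fx = disjoint_fixture
    cm = build_community(fx.members(), fx.database, fx.medium)
    with pytest.raises(ModelError, match="abundances"):
        formulate(cm, weighted=True)


def test_single_gap_repaired(disjoint_fixture):
    _, _, sol = pipeline(disjoint_fixture)
    assert sol.status == "optimal"
    assert sol.objective_value == disjoint_fixture.expected_min_repair == 2
    assert sol.added == {"org0": ["CH0_2"], "org1": ["CH1_1"]}


def test_crossfeeding_substitutes_for_repair(crossfed_fixture):
    """Member 1's deficiency is covered by a metabolite member 0 secretes,
    so only member 0's own gap needs a database reaction."""
    _, _, sol = pipeline(crossfed_fixture)
    assert sol.objective_value == 1
    assert sol.added["org0"] == ["CH0_2"]
    assert sol.added["org1"] == []


def test_growing_community_needs_nothing(intact_fixture):
    _, _, sol = pipeline(intact_fixture)
    assert sol.objective_value == 0
    assert sol.support == frozenset()


def test_zero_objective_without_candidates(intact_fixture):
    fx = intact_fixture
    cm = build_community(fx.members(), ReactionDatabase(), fx.medium)
    sol = solve(formulate(cm))
    assert sol.status == "optimal" and sol.objective_value == 0


def test_infeasible_reports_failing_member(disjoint_fixture):
    """Dropping org1's only repair from the database leaves its floor
    unreachable; the solution says so."""
    fx = disjoint_fixture
    raw = {rid: r for rid, r in fx.database.reactions.items() if rid != "CH1_1"}
    db = ReactionDatabase(reactions=raw,
                          metabolite_catalog=fx.database.metabolite_catalog)
    cm = build_community(fx.members(), db, fx.medium)
    sol = solve(formulate(cm))
    assert sol.status == "infeasible"
    assert sol.solver_meta["infeasible_members"] == ["org1"]


def test_solution_satisfies_all_constraints(solved_random_batch):
    """Steady state per compartment and pool row, binary gating, and growth
    floors hold for every returned solution."""
    for fx, cm, problem, sol in solved_random_batch:
        if sol.status != "optimal":
            continue
        sys = problem.system
        v = np.array([sol.fluxes[vid] for vid in sys.var_ids])
        assert np.abs(sys.A @ v).max() <= 1e-6
        support = sol.support
        for org, base, rid in problem.binaries:
            if (org, base) not in support:
                assert abs(sol.fluxes[rid]) <= 1e-6
        for comp in cm.members:
            assert sol.fluxes[comp.biomass_reaction_id] >= comp.min_growth - 1e-6
        # flux bounds, including FVA-tightened candidate windows
        active = [
            sys.var_index[rid] for org, base, rid in problem.binaries
            if (org, base) in support
        ]
        for j in active:
            assert sys.lb[j] - 1e-6 <= v[j] <= sys.ub[j] + 1e-6


def test_optimum_is_irreducible(solved_random_batch):
    """Removing any single added reaction from an optimal support makes the
    fixed-binary LP infeasible."""
    checked = 0
    for fx, cm, problem, sol in solved_random_batch:
        if sol.status != "optimal" or not sol.support:
            continue
        for drop in sol.support:
            reduced = Support(sol.support - {drop})
            sys = problem.system.with_bounds(problem.support_bounds(reduced))
            assert not sys.feasible(), (
                f"seed fixture {fx.spec.seed}: support stays feasible "
                f"without {drop}"
            )
            checked += 1
    assert checked > 0


def test_single_member_reduces_to_classical_gapfilling():
    """N=1 is ordinary gap-filling; the MILP matches the exhaustive oracle."""
    for seed in (30, 31, 32, 33):
        fx = random_fixture(seed, n_members=1)
        _, _, sol = pipeline(fx)
        assert sol.objective_value == fx.expected_min_repair


def test_weighted_with_unit_abundance_matches_unweighted():
    fx = random_fixture(41, n_members=1)
    cm = build_community(
        fx.members(), fx.database, fx.medium, abundances={fx.models[0].id: 1.0}
    )
    cm, _ = reduce_community(cm)
    plain = solve(formulate(cm, weighted=False))
    weighted = solve(formulate(cm, weighted=True))
    assert weighted.objective_value == plain.objective_value
    assert weighted.support == plain.support


def test_weighted_pool_rows_carry_abundances(disjoint_fixture):
    fx = disjoint_fixture
    cm = build_community(
        fx.members(), fx.database, fx.medium,
        abundances={"org0": 0.66, "org1": 0.34},
    )
    sys = community_system(cm, weights=cm.abundances)
    A = sys.A.tocsc()
    rows = {rid: i for i, rid in enumerate(sys.row_ids)}
    pm = cm.pool["sub0"]
    col = sys.var_index[pm.member_links["org0"]]
    assert A[rows[pm.pool_id], col] == pytest.approx(0.66)
    # the weighted community still solves, and its solution balances the
    # weighted pool rows
    sol = solve(formulate(cm, weighted=True))
    v = np.array([sol.fluxes[vid] for vid in sys.var_ids])
    assert np.abs(sys.A @ v).max() <= 1e-6


def _with_alternative_repair(fx):
    """Add a second, equivalent repair for org0's gap under a fresh id."""
    raw = dict(fx.database.reactions)
    alt = raw["CH0_2"].copy(id="ALT0")
    raw["ALT0"] = alt
    return ReactionDatabase(
        reactions=raw, metabolite_catalog=fx.database.metabolite_catalog
    )


def test_enumeration_finds_symmetric_optima():
    fx = make_linear_fixture(
        FixtureSpec(n_members=1, chain_length=4, n_db_total=3,
                    planted_gaps={0: [2]}, seed=21)
    )
    db = _with_alternative_repair(fx)
    cm, _ = reduce_community(build_community(fx.members(), db, fx.medium))
    problem = formulate(cm)
    res = enumerate_alternatives(problem, k=5, allow_suboptimal=False)
    assert res.exhaustive_at_optimum
    supports = {sol.support for sol in res.solutions}
    assert supports == {
        frozenset({("org0", "CH0_2")}),
        frozenset({("org0", "ALT0")}),
    }


def test_enumeration_k1_equals_solve(disjoint_fixture):
    _, problem, sol = pipeline(disjoint_fixture)
    res = enumerate_alternatives(problem, k=1)
    assert len(res.solutions) == 1
    assert res.solutions[0].support == sol.support


def test_enumeration_suboptimal_tail_grows(disjoint_fixture):
    """With a unique optimum, later solutions have strictly larger supports
    and the objective sequence is non-decreasing."""
    _, problem, _ = pipeline(disjoint_fixture)
    res = enumerate_alternatives(problem, k=3, allow_suboptimal=True)
    objs = [s.objective_value for s in res.solutions]
    assert objs == sorted(objs)
    assert len({s.support for s in res.solutions}) == len(res.solutions)
    if len(objs) > 1:
        assert objs[1] > objs[0]


def test_enumeration_is_deterministic(disjoint_fixture):
    _, problem, _ = pipeline(disjoint_fixture)
    a = enumerate_alternatives(problem, k=4)
    b = enumerate_alternatives(problem, k=4)
    assert [s.support for s in a.solutions] == [s.support for s in b.solutions]


def test_apply_and_verify_restores_growth(disjoint_fixture):
    fx = disjoint_fixture
    cm, _, sol = pipeline(fx)
    filled, growth = apply_and_verify(fx.models[0], sol, fx.database, cm)
    assert growth >= 0.1 - 1e-6
    # the added reaction is materialized with the database's original
    # reversible bounds, not the FVA-tightened window
    assert "CH0_2" in filled.reactions
    assert (filled.reactions["CH0_2"].lb, filled.reactions["CH0_2"].ub) == (
        -1000.0, 1000.0,
    )


def test_apply_empty_solution_is_identity(intact_fixture):
    fx = intact_fixture
    cm, _, sol = pipeline(fx)
    filled, growth = apply_and_verify(fx.models[0], sol, fx.database, cm)
    assert set(filled.reactions) == set(fx.models[0].reactions)
    assert growth == pytest.approx(10.0, abs=1e-6)
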