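"""Community assembly: compartments, pool wiring, media."""

import numpy as np
import pytest

from comgapfill import (
    Medium,
    ModelError,
    ReactionDatabase,
    apply_medium,
    build_community,
    build_compartment,
    community_system,
)
from comgapfill.community import TRANSFER_PREFIX, compartment_system
from comgapfill.fixtures import FixtureSpec, make_linear_fixture


@pytest.fixture(scope="module")
def fx():
    return make_linear_fixture(
        FixtureSpec(
            n_members=2, chain_length=4, n_db_total=6,
            planted_gaps={0: [2], 1: [1]}, seed=1,
        )
    )


def test_compartment_namespacing_and_split(fx):
    model = fx.models[0]
    comp = build_compartment(model, fx.database, "A", 0.1)
    assert comp.model_reaction_ids & comp.database_reaction_ids == set()
    # exchanges are dropped (replaced by pool transfers at community level)
    n_model_kept = sum(1 for r in model.reactions.values() if not r.is_exchange)
    assert len(comp.model_reaction_ids) == n_model_kept
    assert all(rid.endswith("__A") for rid in comp.reactions)
    # the member's own gap reaction is a candidate here
    assert "CH0_2__A" in comp.database_reaction_ids


def test_duplicate_candidates_not_grafted(fx):
    model = fx.models[0]
    db = fx.database
    # CH0_3 exists in the model; a database copy must not be duplicated
    raw = dict(db.reactions)
    raw["CH0_3"] = model.reactions["CH0_3"].copy(lb=-1000.0, ub=1000.0)
    db2 = ReactionDatabase(reactions=raw, metabolite_catalog=db.metabolite_catalog)
    comp = build_compartment(model, db2, "A", 0.1)
    assert "CH0_3__A" in comp.model_reaction_ids
    assert "CH0_3__A" not in comp.database_reaction_ids

    # same stoichiometry under a different id and scale is also deduped
    scaled = model.reactions["CH0_3"].copy(id="ALIAS")
    scaled.stoichiometry = {m: 2 * c for m, c in scaled.stoichiometry.items()}
    raw["ALIAS"] = scaled
    db3 = ReactionDatabase(reactions=raw, metabolite_catalog=db.metabolite_catalog)
    comp3 = build_compartment(model, db3, "A", 0.1)
    assert "ALIAS__A" not in comp3.reactions


def test_empty_database_is_identity(fx):
    model = fx.models[0]
    comp = build_compartment(model, ReactionDatabase(), "A", 0.1)
    n_model_kept = sum(1 for r in model.reactions.values() if not r.is_exchange)
    assert len(comp.reactions) == n_model_kept
    assert not comp.database_reaction_ids


def test_duplicate_tags_rejected(fx):
    with pytest.raises(ModelError, match="tag"):
        build_community(
            [(fx.models[0], 0.1), (fx.models[0], 0.1)], fx.database, fx.medium
        )


def test_symmetric_community_shares_pool(fx):
    m0 = fx.models[0]
    twin = m0.copy()
    twin.id = "org0_twin"
    # the shared medium also names org1's substrate, unused by either twin
    with pytest.warns(UserWarning, match="sub1"):
        cm = build_community(
            [(m0, 0.1), (twin, 0.1)], fx.database, fx.medium, tags=["a", "b"]
        )
    assert len(cm.members) == 2
    assert "sub0" in cm.pool
    assert set(cm.pool["sub0"].member_links) == {"org0", "org0_twin"}


def test_pool_covers_member_and_medium_metabolites(fx):
    cm = build_community(fx.members(), fx.database, fx.medium)
    assert {"sub0", "sub1"} <= set(cm.pool)
    medium = Medium(bounds={**fx.medium.bounds, "phantom": (0.0, 10.0)})
    with pytest.warns(UserWarning, match="phantom"):
        cm2 = build_community(fx.members(), fx.database, medium)
    assert cm2.pool["phantom"].member_links == {}


def test_transfer_and_pool_rows(fx):
    """Transfer columns: -1 on the member's extracellular species, +1 on the
    pool species; pool row is exactly -v_env + sum_n v_transfer."""
    cm = build_community(fx.members(), fx.database, fx.medium)
    sys = community_system(cm)
    A = sys.A.tocsc()
    rows = {rid: i for i, rid in enumerate(sys.row_ids)}
    for base, pm in cm.pool.items():
        pool_row = rows[pm.pool_id]
        col = sys.var_index[pm.environment_exchange_id]
        assert A[pool_row, col] == -1.0
        for comp in cm.members:
            if comp.organism_id not in pm.member_links:
                continue
            col = sys.var_index[pm.member_links[comp.organism_id]]
            column = A[:, col].toarray().ravel()
            assert column[rows[comp.ext_metabolites[base]]] == -1.0
            assert column[pool_row] == 1.0
            assert np.count_nonzero(column) == 2


def test_reaction_count_identity(fx):
    cm = build_community(fx.members(), fx.database, fx.medium)
    sys = community_system(cm)
    expected = sum(
        len(c.model_reaction_ids) + len(c.database_reaction_ids) for c in cm.members
    ) + sum(len(pm.member_links) + 1 for pm in cm.pool.values())
    assert sys.n_vars == expected


def test_single_member_fba_equivalence(intact_fixture):
    """One member, empty database, open medium: community FBA equals the
    standalone model's optimum (uptake 10 through a unit chain -> growth 10)."""
    fx = intact_fixture
    cm = build_community(fx.members(), ReactionDatabase(), fx.medium)
    sys = community_system(cm)
    growth, _ = sys.optimize({cm.members[0].biomass_reaction_id: 1.0}, "max")
    assert growth == pytest.approx(10.0, abs=1e-6)


def test_apply_medium_policies_and_idempotence(fx):
    cm = build_community(fx.members(), fx.database, fx.medium)
    # open_secretion_only: unlisted pool metabolites can accumulate, not enter
    assert cm.medium.environment_bounds("unlisted", cm.cap) == (0.0, 1000.0)
    closed = Medium(bounds=dict(fx.medium.bounds), default_policy="closed")
    cm2 = apply_medium(cm, closed)
    assert cm2.medium.environment_bounds("unlisted", cm2.cap) == (0.0, 0.0)
    # named entries are taken verbatim
    assert cm2.medium.environment_bounds("sub0", cm2.cap) == (-10.0, 1000.0)
    cm3 = apply_medium(cm2, closed)
    sys2 = community_system(cm2)
    sys3 = community_system(cm3)
    assert sys2.var_ids == sys3.var_ids
    assert np.array_equal(sys2.lb, sys3.lb) and np.array_equal(sys2.ub, sys3.ub)


def test_anaerobic_style_shutoff(fx):
    """A (0,0) medium entry makes uptake of that metabolite impossible."""
    shut = Medium(bounds={**fx.medium.bounds, "sub0": (0.0, 0.0)})
    cm = apply_medium(build_community(fx.members(), fx.database, fx.medium), shut)
    sys = community_system(cm, relax_growth=True)
    lo, hi = sys.flux_range(cm.pool["sub0"].member_links["org0"])
    assert hi <= 1e-9  # org0 cannot import its substrate any more


def test_medium_rejects_inverted_bounds():
    with pytest.raises(ValueError, match="lb"):
        Medium(bounds={"glc__D": (5.0, -5.0)})


def test_member_scoped_bounds_apply_to_transfers(fx):
    medium = Medium(
        bounds=dict(fx.medium.bounds),
        member_bounds={("org0", "sub0"): (-2.0, 0.0)},
    )
    cm = build_community(fx.members(), fx.database, medium)
    sys = community_system(cm)
    j = sys.var_index[cm.pool["sub0"].member_links["org0"]]
    assert (sys.lb[j], sys.ub[j]) == (-2.0, 0.0)


def test_compartment_system_boundary_modes(fx):
    comp = build_compartment(fx.models[0], fx.database, "A", 0.1)
    open_sys = compartment_system(comp, open_transfers=True)
    j = open_sys.var_index[f"{TRANSFER_PREFIX}sub0__A"]
    assert (open_sys.lb[j], open_sys.ub[j]) == (-1000.0, 1000.0)
    closed_sys = compartment_system(comp, open_transfers=False, medium=fx.medium)
    j = closed_sys.var_index[f"{TRANSFER_PREFIX}sub0__A"]
    assert (closed_sys.lb[j], closed_sys.ub[j]) == (-10.0, 1000.0)
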