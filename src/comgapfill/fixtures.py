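"""Synthetic communities with known minimal repairs and cross-feeding.

The generator plants gaps in small linear-chain metabolisms so that every
core behavior — gap repair, pool-mediated rescue, FVA pruning of dead
candidates, alternative optima — is exercised with a ground truth computed
by an exhaustive oracle at generation time. All networks are mass-balanced
by construction: every metabolite carries the unit pseudo-formula "X"
(charge 0), which decouples fixture logic from formula parsing.

Each member n is a chain

    sub{n}_e  -UPT->  m{n}_1  -CH->  ...  -CH->  m{n}_L  -BIO-> (biomass)

with its substrate supplied by the medium at -10 flux units. A planted gap
moves one chain reaction into the shared database; a planted exchange gives
a donor member a side reaction secreting an intermediate that a receiver
can convert past its own gap, so cross-feeding can substitute for a repair.
Decoy database reactions over fresh, disconnected metabolites pad the
candidate pool and are pruned by FVA.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .community import Medium, build_community
from .gapfill import Support
from .model import (
    DEFAULT_FLUX_CAP,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    ReactionDatabase,
)

SUBSTRATE_UPTAKE = 10.0
DEFAULT_FLOOR = 0.1


@dataclass
class FixtureSpec:
    """Deterministic recipe for one synthetic community."""

    n_members: int = 2
    chain_length: int = 4
    n_db_total: int = 6
    planted_gaps: dict[int, list[int]] = field(default_factory=dict)
    # member index -> chain positions (1-based; position k removes CH{n}_{k})
    planted_exchanges: list[tuple[int, int]] = field(default_factory=list)
    # (donor member, receiver member): donor can secrete a bypass metabolite
    growth_floor: float = DEFAULT_FLOOR
    seed: int = 0

    def validate(self) -> None:
        if self.n_members < 1 or self.chain_length < 2:
            raise ModelError("need >=1 member and chain_length >=2")
        for n, gaps in self.planted_gaps.items():
            if not 0 <= n < self.n_members:
                raise ModelError(f"gap member {n} out of range")
            for g in gaps:
                if not 1 <= g < self.chain_length:
                    raise ModelError(f"gap position {g} out of range")
        n_gaps = sum(len(v) for v in self.planted_gaps.values())
        if self.n_db_total < n_gaps:
            raise ModelError("n_db_total smaller than number of planted gaps")


@dataclass
class Fixture:
    spec: FixtureSpec
    models: list[MetabolicModel]
    database: ReactionDatabase
    medium: Medium
    growth_floors: dict[str, float]
    expected_min_repair: int
    oracle_supports: list[Support]

    def members(self) -> list[tuple[MetabolicModel, float]]:
        return [(m, self.growth_floors[m.id]) for m in self.models]

    def to_json(self) -> str:
        """Canonical serialization (sorted keys) for determinism checks."""
        payload = {
            "spec": {**asdict(self.spec),
                     "planted_gaps": {str(k): v for k, v in
                                      sorted(self.spec.planted_gaps.items())},
                     "planted_exchanges": [list(t) for t in
                                           self.spec.planted_exchanges]},
            "models": [
                {
                    "id": m.id,
                    "biomass": m.biomass_reaction_id,
                    "metabolites": {
                        mid: [met.formula, met.charge, met.compartment]
                        for mid, met in sorted(m.metabolites.items())
                    },
                    "reactions": {
                        rid: [sorted(r.stoichiometry.items()), r.lb, r.ub,
                              r.is_exchange, r.is_biomass]
                        for rid, r in sorted(m.reactions.items())
                    },
                }
                for m in self.models
            ],
            "database": {
                rid: [sorted(r.stoichiometry.items()), r.lb, r.ub]
                for rid, r in sorted(self.database.reactions.items())
            },
            "medium": {k: list(v) for k, v in sorted(self.medium.bounds.items())},
            "growth_floors": dict(sorted(self.growth_floors.items())),
            "expected_min_repair": self.expected_min_repair,
            "oracle_supports": sorted(sorted(s) for s in self.oracle_supports),
        }
        return json.dumps(payload, sort_keys=True)


def _pseudo(mid: str, compartment: str = "c") -> Metabolite:
    return Metabolite(id=mid, formula="X", charge=0, compartment=compartment)


def _member_model(spec: FixtureSpec, n: int) -> tuple[MetabolicModel, dict[str, Reaction]]:
    """Build member n's full (ungapped) chain; returns (model, chain reactions)."""
    L = spec.chain_length
    model = MetabolicModel(id=f"org{n}")
    sub = f"sub{n}_e"
    model.metabolites[sub] = _pseudo(sub, "e")
    for k in range(1, L + 1):
        mid = f"m{n}_{k}"
        model.metabolites[mid] = _pseudo(mid)
    chain: dict[str, Reaction] = {}
    model.reactions[f"UPT{n}"] = Reaction(
        id=f"UPT{n}", stoichiometry={sub: -1.0, f"m{n}_1": 1.0},
        lb=0.0, ub=DEFAULT_FLUX_CAP,
    )
    for k in range(1, L):
        rid = f"CH{n}_{k}"
        rxn = Reaction(
            id=rid,
            stoichiometry={f"m{n}_{k}": -1.0, f"m{n}_{k + 1}": 1.0},
            lb=0.0, ub=DEFAULT_FLUX_CAP,
        )
        model.reactions[rid] = rxn
        chain[rid] = rxn
    model.reactions[f"BIO{n}"] = Reaction(
        id=f"BIO{n}", stoichiometry={f"m{n}_{L}": -1.0},
        lb=0.0, ub=DEFAULT_FLUX_CAP, is_biomass=True,
    )
    model.reactions[f"EX_{sub}"] = Reaction(
        id=f"EX_{sub}", stoichiometry={sub: -1.0},
        lb=-DEFAULT_FLUX_CAP, ub=DEFAULT_FLUX_CAP, is_exchange=True,
    )
    model.biomass_reaction_id = f"BIO{n}"
    return model, chain


def make_linear_fixture(spec: FixtureSpec) -> Fixture:
    """Generate the community described by ``spec``; deterministic per seed.

    ``expected_min_repair`` and all minimum supports are computed by the
    brute-force oracle at generation time; generation fails if the fully
    repaired community cannot reach the stated floors.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    models: list[MetabolicModel] = []
    db_reactions: dict[str, Reaction] = {}
    catalog: dict[str, Metabolite] = {}

    for n in range(spec.n_members):
        model, chain = _member_model(spec, n)
        for g in sorted(spec.planted_gaps.get(n, [])):
            rid = f"CH{n}_{g}"
            rxn = model.reactions.pop(rid)
            db_reactions[rid] = rxn.copy(lb=-DEFAULT_FLUX_CAP, ub=DEFAULT_FLUX_CAP)
            for mid in rxn.stoichiometry:
                catalog[mid] = _pseudo(mid)
        models.append(model)

    for idx, (donor, receiver) in enumerate(spec.planted_exchanges):
        base = f"x{idx}_{donor}{receiver}"
        ext = f"{base}_e"
        dm, rm = models[donor], models[receiver]
        for m in (dm, rm):
            m.metabolites[ext] = _pseudo(ext, "e")
        # donor secretes the bypass metabolite from mid-chain surplus
        tap = max(1, spec.chain_length // 2)
        dm.reactions[f"SEC{donor}_{idx}"] = Reaction(
            id=f"SEC{donor}_{idx}",
            stoichiometry={f"m{donor}_{tap}": -1.0, ext: 1.0},
            lb=0.0, ub=DEFAULT_FLUX_CAP,
        )
        dm.reactions[f"EX_{ext}__{donor}"] = Reaction(
            id=f"EX_{ext}__{donor}", stoichiometry={ext: -1.0},
            lb=-DEFAULT_FLUX_CAP, ub=DEFAULT_FLUX_CAP, is_exchange=True,
        )
        # receiver converts it to the step just past its first gap
        gaps = sorted(spec.planted_gaps.get(receiver, []))
        target = f"m{receiver}_{gaps[0] + 1}" if gaps else f"m{receiver}_1"
        rm.reactions[f"CNV{receiver}_{idx}"] = Reaction(
            id=f"CNV{receiver}_{idx}",
            stoichiometry={ext: -1.0, target: 1.0},
            lb=0.0, ub=DEFAULT_FLUX_CAP,
        )
        rm.reactions[f"EX_{ext}__{receiver}"] = Reaction(
            id=f"EX_{ext}__{receiver}", stoichiometry={ext: -1.0},
            lb=-DEFAULT_FLUX_CAP, ub=DEFAULT_FLUX_CAP, is_exchange=True,
        )

    n_decoys = spec.n_db_total - len(db_reactions)
    for i in range(n_decoys):
        a, b = f"d{i}_a", f"d{i}_b"
        catalog[a] = _pseudo(a)
        catalog[b] = _pseudo(b)
        rid = f"DEC{i}"
        db_reactions[rid] = Reaction(
            id=rid, stoichiometry={a: -1.0, b: 1.0},
            lb=-DEFAULT_FLUX_CAP, ub=DEFAULT_FLUX_CAP,
        )
    # seeded shuffle fixes the (sorted-anyway) decoy naming; keeps rng in the API
    rng.permutation(max(n_decoys, 1))

    medium = Medium(
        bounds={f"sub{n}": (-SUBSTRATE_UPTAKE, DEFAULT_FLUX_CAP)
                for n in range(spec.n_members)},
        default_policy="open_secretion_only",
    )
    floors = {f"org{n}": spec.growth_floor for n in range(spec.n_members)}
    database = ReactionDatabase(
        reactions=db_reactions, metabolite_catalog=catalog,
        provenance=f"synthetic fixture seed={spec.seed}",
    )

    supports = oracle_gapfill(
        [(m, floors[m.id]) for m in models], database, medium, floors
    )
    if not supports and sum(len(v) for v in spec.planted_gaps.values()) > 0:
        # supports == [frozenset()] means feasible with 0 additions; an empty
        # list means infeasible even with the full database
        raise ModelError(f"fixture seed={spec.seed}: not repairable from database")
    expected = len(next(iter(supports))) if supports else -1
    if expected < 0:
        raise ModelError(f"fixture seed={spec.seed}: infeasible community")

    return Fixture(
        spec=spec,
        models=models,
        database=database,
        medium=medium,
        growth_floors=floors,
        expected_min_repair=expected,
        oracle_supports=supports,
    )


def random_fixture(seed: int, *, n_members: int | None = None) -> Fixture:
    """A randomized small community for property suites; deterministic per seed."""
    rng = np.random.default_rng(seed)
    n = n_members or int(rng.integers(1, 4))
    chain = int(rng.integers(3, 6))
    # the oracle enumerates (member, candidate) pairs, so keep
    # n_members * n_db small enough for exhaustive search
    max_db = max(2, 16 // n)
    max_gaps_per_member = 1 if n >= 3 else 2
    gaps: dict[int, list[int]] = {}
    for m in range(n):
        k = int(rng.integers(0, max_gaps_per_member + 1))
        if k:
            gaps[m] = sorted(
                int(g) for g in rng.choice(np.arange(1, chain), size=k, replace=False)
            )
    exchanges = []
    if n >= 2 and rng.random() < 0.5:
        donor, receiver = rng.choice(n, size=2, replace=False)
        exchanges.append((int(donor), int(receiver)))
    n_gaps = sum(len(v) for v in gaps.values())
    n_db = min(max_db, max(n_gaps + int(rng.integers(1, 4)), 1))
    if n_db < n_gaps:  # unreachable with the caps above, kept defensive
        n_db = n_gaps
    spec = FixtureSpec(
        n_members=n, chain_length=chain, n_db_total=n_db,
        planted_gaps=gaps, planted_exchanges=exchanges, seed=seed,
    )
    return make_linear_fixture(spec)


def knockout(
    model: MetabolicModel,
    reaction_ids: list[str],
    *,
    prune_orphans: bool = False,
) -> MetabolicModel:
    """Delete reactions from a copy of the model (paper-style strain building)."""
    unknown = [rid for rid in reaction_ids if rid not in model.reactions]
    if unknown:
        raise ModelError(f"unknown reaction ids: {unknown}")
    out = model.copy()
    for rid in reaction_ids:
        del out.reactions[rid]
    if prune_orphans:
        used = {m for r in out.reactions.values() for m in r.stoichiometry}
        out.metabolites = {
            mid: met for mid, met in out.metabolites.items() if mid in used
        }
    out.validate()
    return out


def oracle_gapfill(
    members: list[tuple[MetabolicModel, float]],
    database: ReactionDatabase,
    medium: Medium,
    floors: dict[str, float],
    *,
    max_candidates: int = 16,
) -> list[Support]:
    """All minimum-cardinality repair supports, by exhaustive search.

    Breadth-first over support subsets in increasing cardinality, testing
    LP feasibility of the community with exactly those candidates active.
    Ground truth for MILP equivalence testing; independent of the MILP path
    (no binaries, plain LP feasibility per subset). Returns [] when the
    community is infeasible even with the full database.
    """
    from .gapfill import formulate  # local import to avoid cycle at module load

    cm = build_community(members, database, medium)
    problem = formulate(cm, growth_floors=floors)
    candidates = [(org, base) for org, base, _ in problem.binaries]
    if len(candidates) > max_candidates:
        raise ModelError(
            f"{len(candidates)} candidates exceed the oracle cap {max_candidates}"
        )

    full = Support(candidates)
    sys_full = problem.system.with_bounds(problem.support_bounds(full))
    if not sys_full.feasible():
        return []

    for size in range(len(candidates) + 1):
        hits = []
        for combo in itertools.combinations(candidates, size):
            support = Support(combo)
            sys = problem.system.with_bounds(problem.support_bounds(support))
            if sys.feasible():
                hits.append(support)
        if hits:
            return hits
    return []
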