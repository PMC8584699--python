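"""Assembly of the compartmentalized community model.

Each organism becomes one namespaced compartment holding its own reactions
(J_Model) plus candidate database reactions (J_Database). Compartments
exchange metabolites only through a common pool: per member and pool
metabolite a reversible transfer reaction (v_ex^n), and per pool metabolite
one environment exchange (v_ex^c) whose bounds come from the medium. The
pool steady-state row is

    -v_ex(i)^c + sum_n w_n * v_ex(i)^n = 0

with w_n = 1, or the member's relative abundance in the abundance-weighted
variant (member fluxes are per gDW of that member, so weighting restores a
community-level mass balance).

Sign conventions follow COBRA: uptake from the pool/environment is negative
flux; a transfer reaction has coefficient -1 on the member's extracellular
species and +1 on the pool species, so positive transfer flux is secretion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

from ._linalg import LinearSystem
from .model import (
    DEFAULT_FLUX_CAP,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    ReactionDatabase,
)

TRANSFER_PREFIX = "TP_"
ENV_PREFIX = "EP_"


def base_metabolite_id(met: Metabolite) -> str | None:
    """Base id of an extracellular species, or None if not extracellular.

    Pool identity is the BiGG-style base id after stripping the "_e"
    compartment suffix; members exchange a metabolite iff their
    extracellular species share a base id (shared namespace assumed).
    """
    if met.compartment == "e" or met.id.endswith("_e"):
        return met.id[:-2] if met.id.endswith("_e") else met.id
    return None


@dataclass
class Medium:
    """Bounds on environment exchanges v_ex(i)^c, uptake-negative convention.

    ``default_policy`` governs pool metabolites without an explicit entry:
    ``open_secretion_only`` -> (0, +cap) (may accumulate, never imported);
    ``closed`` -> (0, 0). ``member_bounds`` carries member-scoped transfer
    limits keyed by (organism_id, base_id), e.g. a member permitted only to
    uptake or only to excrete a given acid.
    """

    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    default_policy: str = "open_secretion_only"
    member_bounds: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.default_policy not in ("open_secretion_only", "closed"):
            raise ValueError(f"unknown default_policy {self.default_policy!r}")
        for base, (lo, hi) in {**self.bounds, **self.member_bounds}.items():
            if lo > hi:
                raise ValueError(f"medium entry {base}: lb {lo} > ub {hi}")

    def environment_bounds(self, base_id: str, cap: float) -> tuple[float, float]:
        if base_id in self.bounds:
            return self.bounds[base_id]
        if self.default_policy == "open_secretion_only":
            return (0.0, cap)
        return (0.0, 0.0)


@dataclass
class OrganismCompartment:
    """One member's namespaced network plus its candidate database reactions."""

    organism_id: str
    tag: str
    reactions: dict[str, Reaction]
    metabolites: dict[str, Metabolite]
    model_reaction_ids: set[str]
    database_reaction_ids: set[str]
    ext_metabolites: dict[str, str]  # base id -> namespaced extracellular met id
    biomass_reaction_id: str
    min_growth: float
    cap: float = DEFAULT_FLUX_CAP

    def copy(self) -> "OrganismCompartment":
        return replace(
            self,
            reactions={rid: r.copy() for rid, r in self.reactions.items()},
            metabolites=dict(self.metabolites),
            model_reaction_ids=set(self.model_reaction_ids),
            database_reaction_ids=set(self.database_reaction_ids),
            ext_metabolites=dict(self.ext_metabolites),
        )


@dataclass
class PoolMetabolite:
    base_id: str
    pool_id: str
    member_links: dict[str, str]  # organism_id -> transfer reaction id
    environment_exchange_id: str


@dataclass
class CommunityModel:
    members: list[OrganismCompartment]
    pool: dict[str, PoolMetabolite]
    medium: Medium
    abundances: dict[str, float] | None = None
    cap: float = DEFAULT_FLUX_CAP

    def member(self, organism_id: str) -> OrganismCompartment:
        for comp in self.members:
            if comp.organism_id == organism_id:
                return comp
        raise KeyError(organism_id)

    def validate(self) -> None:
        tags = [c.tag for c in self.members]
        if len(set(tags)) != len(tags):
            raise ModelError("member tags not unique")
        for pm in self.pool.values():
            for org in pm.member_links:
                self.member(org)
        if self.abundances is not None:
            total = sum(self.abundances.values())
            if abs(total - 1.0) > 1e-6:
                raise ModelError(f"abundances sum to {total}, expected 1")


def namespaced(identifier: str, tag: str) -> str:
    return f"{identifier}__{tag}"


def _canonical_stoichiometry(stoich: dict[str, float]) -> tuple:
    """Scale-and-direction-invariant signature, for duplicate detection."""
    items = sorted(stoich.items())
    scale = items[0][1]
    return tuple((m, round(c / scale, 9)) for m, c in items)


def build_compartment(
    model: MetabolicModel,
    db: ReactionDatabase,
    tag: str,
    min_growth: float,
    *,
    cap: float = DEFAULT_FLUX_CAP,
) -> OrganismCompartment:
    """Namespace a member model and graft the candidate database onto it.

    Database reactions already present in the model (same id, or same
    canonical stoichiometry up to scale/direction) are not duplicated.
    Candidates enter reversible at (-cap, +cap); metabolites they reference
    that the model lacks are created in the compartment (such dead-end
    candidates are pruned later by FVA). The model's original exchange
    reactions are dropped — pool transfer reactions replace them.
    """
    if min_growth < 0:
        raise ModelError(f"{model.id}: min_growth must be >= 0")
    if model.biomass_reaction_id is None:
        raise ModelError(f"model {model.id} has no biomass reaction")
    model.validate()

    metabolites: dict[str, Metabolite] = {}
    for met in model.metabolites.values():
        metabolites[namespaced(met.id, tag)] = replace(met, id=namespaced(met.id, tag))

    reactions: dict[str, Reaction] = {}
    model_ids: set[str] = set()
    signatures: dict[tuple, str] = {}
    for rxn in model.reactions.values():
        if rxn.is_exchange:
            continue  # replaced by pool transfers
        nid = namespaced(rxn.id, tag)
        nr = rxn.copy(
            id=nid,
            stoichiometry={namespaced(m, tag): c for m, c in rxn.stoichiometry.items()},
        )
        reactions[nid] = nr
        model_ids.add(nid)
        signatures[_canonical_stoichiometry(rxn.stoichiometry)] = rxn.id

    db_ids: set[str] = set()
    for rid in sorted(db.reactions):
        rxn = db.reactions[rid]
        if rxn.id in model.reactions:
            continue
        if _canonical_stoichiometry(rxn.stoichiometry) in signatures:
            continue
        nid = namespaced(rxn.id, tag)
        nr = rxn.copy(
            id=nid,
            lb=-cap,
            ub=cap,
            stoichiometry={namespaced(m, tag): c for m, c in rxn.stoichiometry.items()},
        )
        reactions[nid] = nr
        db_ids.add(nid)
        for mid in rxn.stoichiometry:
            nmid = namespaced(mid, tag)
            if nmid not in metabolites:
                proto = db.metabolite_catalog.get(mid, Metabolite(id=mid))
                metabolites[nmid] = replace(proto, id=nmid)

    ext = {}
    for met in model.metabolites.values():
        base = base_metabolite_id(met)
        if base is not None:
            ext[base] = namespaced(met.id, tag)

    return OrganismCompartment(
        organism_id=model.id,
        tag=tag,
        reactions=reactions,
        metabolites=metabolites,
        model_reaction_ids=model_ids,
        database_reaction_ids=db_ids,
        ext_metabolites=ext,
        biomass_reaction_id=namespaced(model.biomass_reaction_id, tag),
        min_growth=min_growth,
        cap=cap,
    )


def build_community(
    members: list[tuple[MetabolicModel, float]],
    db: ReactionDatabase,
    medium: Medium,
    *,
    abundances: dict[str, float] | None = None,
    tags: list[str] | None = None,
    cap: float = DEFAULT_FLUX_CAP,
) -> CommunityModel:
    """Assemble the full community: compartments + common metabolite pool.

    ``members`` is a list of (model, minimum growth rate). One pool
    metabolite is created per distinct extracellular base id appearing in
    any member or in the medium; medium entries naming a base id unknown to
    every member and the database produce a warning and an inert pool entry.
    """
    if not members:
        raise ModelError("community needs at least one member")
    if tags is None:
        tags = [model.id for model, _ in members]
    if len(set(tags)) != len(tags):
        raise ModelError("duplicate compartment tags")
    if abundances is not None:
        total = sum(abundances.values())
        if abs(total - 1.0) > 1e-6:
            raise ModelError(f"abundances sum to {total}, expected 1")

    comps = [
        build_compartment(model, db, tag, floor, cap=cap)
        for (model, floor), tag in zip(members, tags)
    ]

    bases: set[str] = set()
    for comp in comps:
        bases.update(comp.ext_metabolites)
    known_bases = set(bases)
    for base in medium.bounds:
        if base not in known_bases:
            catalog_hit = any(
                base_metabolite_id(m) == base for m in db.metabolite_catalog.values()
            )
            if not catalog_hit:
                warnings.warn(
                    f"medium names metabolite {base!r} absent from all members "
                    "and the database; creating an inert pool entry"
                )
        bases.add(base)

    pool: dict[str, PoolMetabolite] = {}
    for base in sorted(bases):
        links = {
            comp.organism_id: f"{TRANSFER_PREFIX}{base}__{comp.tag}"
            for comp in comps
            if base in comp.ext_metabolites
        }
        pool[base] = PoolMetabolite(
            base_id=base,
            pool_id=f"{base}__pool",
            member_links=links,
            environment_exchange_id=f"{ENV_PREFIX}{base}",
        )

    cm = CommunityModel(
        members=comps, pool=pool, medium=medium, abundances=abundances, cap=cap
    )
    cm.validate()
    return cm


def apply_medium(cm: CommunityModel, medium: Medium) -> CommunityModel:
    """Return the community under a different medium (structure untouched).

    Exchange bounds are derived from the medium at matrix-assembly time, so
    swapping the medium object is complete and idempotent. New medium-only
    metabolites get inert pool entries.
    """
    pool = dict(cm.pool)
    for base in medium.bounds:
        if base not in pool:
            pool[base] = PoolMetabolite(
                base_id=base,
                pool_id=f"{base}__pool",
                member_links={},
                environment_exchange_id=f"{ENV_PREFIX}{base}",
            )
    return replace(cm, pool=pool, medium=medium)


def community_system(
    cm: CommunityModel,
    *,
    growth_floors: dict[str, float] | None = None,
    weights: dict[str, float] | None = None,
    relax_growth: bool = False,
) -> LinearSystem:
    """Assemble the steady-state system over all community fluxes.

    Rows: every namespaced member metabolite (Eq. per-compartment steady
    state) and every pool metabolite (pool balance with weights w_n).
    Variables: member model+database reactions, transfer reactions, and
    environment exchanges, in deterministic (member order, sorted id) order.
    """
    var_ids: list[str] = []
    lbs: list[float] = []
    ubs: list[float] = []
    row_ids: list[str] = []
    row_index: dict[str, int] = {}
    entries: list[tuple[int, int, float]] = []

    def add_row(rid: str) -> int:
        row_index[rid] = len(row_ids)
        row_ids.append(rid)
        return row_index[rid]

    for comp in cm.members:
        for mid in sorted(comp.metabolites):
            add_row(mid)
    for base in sorted(cm.pool):
        add_row(cm.pool[base].pool_id)

    floors = growth_floors or {}
    for comp in cm.members:
        for rid in sorted(comp.reactions):
            rxn = comp.reactions[rid]
            lo, hi = rxn.lb, rxn.ub
            if rid == comp.biomass_reaction_id:
                floor = floors.get(comp.organism_id, comp.min_growth)
                if relax_growth:
                    lo = min(lo, 0.0)
                else:
                    lo = max(lo, floor)
            col = len(var_ids)
            var_ids.append(rid)
            lbs.append(lo)
            ubs.append(hi)
            for mid, coeff in rxn.stoichiometry.items():
                entries.append((row_index[mid], col, coeff))

    w = weights or {}
    for base in sorted(cm.pool):
        pm = cm.pool[base]
        pool_row = row_index[pm.pool_id]
        for comp in cm.members:
            if comp.organism_id not in pm.member_links:
                continue
            tid = pm.member_links[comp.organism_id]
            lo, hi = cm.medium.member_bounds.get(
                (comp.organism_id, base), (-cm.cap, cm.cap)
            )
            col = len(var_ids)
            var_ids.append(tid)
            lbs.append(lo)
            ubs.append(hi)
            entries.append((row_index[comp.ext_metabolites[base]], col, -1.0))
            entries.append((pool_row, col, w.get(comp.organism_id, 1.0)))
        col = len(var_ids)
        var_ids.append(pm.environment_exchange_id)
        lo, hi = cm.medium.environment_bounds(base, cm.cap)
        lbs.append(lo)
        ubs.append(hi)
        entries.append((pool_row, col, -1.0))

    rows, cols, vals = zip(*entries)
    A = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(row_ids), len(var_ids))
    )
    return LinearSystem(var_ids, np.array(lbs), np.array(ubs), A, row_ids)


def compartment_system(
    comp: OrganismCompartment,
    *,
    open_transfers: bool = True,
    medium: Medium | None = None,
    relax_growth: bool = True,
) -> LinearSystem:
    """Steady-state system for one compartment in isolation.

    Each extracellular base id gets a boundary variable standing in for its
    pool transfer. With ``open_transfers`` (the default, used for FVA) these
    are fully open at (-cap, +cap), over-approximating every community
    context; otherwise bounds come from the medium.
    """
    var_ids: list[str] = []
    lbs: list[float] = []
    ubs: list[float] = []
    row_ids = sorted(comp.metabolites)
    row_index = {mid: i for i, mid in enumerate(row_ids)}
    entries: list[tuple[int, int, float]] = []

    for rid in sorted(comp.reactions):
        rxn = comp.reactions[rid]
        lo, hi = rxn.lb, rxn.ub
        if rid == comp.biomass_reaction_id:
            lo = min(lo, 0.0) if relax_growth else max(lo, comp.min_growth)
        col = len(var_ids)
        var_ids.append(rid)
        lbs.append(lo)
        ubs.append(hi)
        for mid, coeff in rxn.stoichiometry.items():
            entries.append((row_index[mid], col, coeff))

    for base in sorted(comp.ext_metabolites):
        col = len(var_ids)
        var_ids.append(f"{TRANSFER_PREFIX}{base}__{comp.tag}")
        if open_transfers or medium is None:
            lo, hi = -comp.cap, comp.cap
        else:
            lo, hi = medium.environment_bounds(base, comp.cap)
            mlo, mhi = medium.member_bounds.get(
                (comp.organism_id, base), (-comp.cap, comp.cap)
            )
            lo, hi = max(lo, mlo), min(hi, mhi)
        lbs.append(lo)
        ubs.append(hi)
        entries.append((row_index[comp.ext_metabolites[base]], col, -1.0))

    rows, cols, vals = zip(*entries)
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(len(row_ids), len(var_ids)))
    return LinearSystem(var_ids, np.array(lbs), np.array(ubs), A, row_ids)
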