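"""Reading and writing models, databases and media.

SBML Level 3 + FBC and COBRA-style JSON are handled by COBRApy; this module
converts between COBRApy objects and the lightweight containers in
:mod:`comgapfill.model`, maps infinite bounds to the global flux cap, and
serializes media and curation reports.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import cobra
import pandas as pd

from .model import (
    DEFAULT_FLUX_CAP,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    ReactionDatabase,
)


def _is_extracellular(met: Metabolite) -> bool:
    return met.compartment == "e" or met.id.endswith("_e")


def _cap(value: float, cap: float) -> float:
    if value is None or math.isinf(value):
        return math.copysign(cap, value if value is not None else 1.0)
    return float(value)


def from_cobra(
    cm: "cobra.Model",
    *,
    cap: float = DEFAULT_FLUX_CAP,
    biomass_reaction_id: str | None = None,
) -> MetabolicModel:
    """Convert a COBRApy model, clamping infinite bounds to ±cap.

    The biomass reaction is taken from the FBC objective; if the objective is
    empty, a case-insensitive "biomass" id/name match is tried; otherwise the
    caller must name it explicitly.
    """
    model = MetabolicModel(id=cm.id or "model")
    for met in cm.metabolites:
        charge = met.charge
        model.metabolites[met.id] = Metabolite(
            id=met.id,
            name=met.name or "",
            formula=met.formula or None,
            charge=int(charge) if charge is not None else None,
            compartment=met.compartment or "c",
        )
    objective_ids = {r.id for r in cm.reactions if r.objective_coefficient}
    if biomass_reaction_id is None:
        if objective_ids:
            biomass_reaction_id = sorted(objective_ids)[0]
        else:
            candidates = [
                r.id
                for r in cm.reactions
                if "biomass" in r.id.lower() or "biomass" in (r.name or "").lower()
            ]
            if candidates:
                biomass_reaction_id = sorted(candidates)[0]
    boundary_ids = {r.id for r in cm.boundary}
    for rxn in cm.reactions:
        stoich = {m.id: float(c) for m, c in rxn.metabolites.items()}
        # a boundary reaction is an exchange only when it moves an
        # extracellular species; sinks/demands on internal metabolites
        # (including drain-style biomass reactions) are kept as ordinary
        # reactions
        is_exchange = (
            len(stoich) == 1
            and rxn.id in boundary_ids
            and rxn.id != biomass_reaction_id
            and _is_extracellular(model.metabolites[next(iter(stoich))])
        )
        model.reactions[rxn.id] = Reaction(
            id=rxn.id,
            name=rxn.name or "",
            stoichiometry=stoich,
            lb=_cap(rxn.lower_bound, cap),
            ub=_cap(rxn.upper_bound, cap),
            is_exchange=is_exchange,
            is_biomass=rxn.id == biomass_reaction_id,
        )
    model.biomass_reaction_id = biomass_reaction_id
    model.validate()
    return model


def to_cobra(model: MetabolicModel) -> "cobra.Model":
    cm = cobra.Model(model.id)
    mets = {}
    for met in model.metabolites.values():
        m = cobra.Metabolite(
            met.id,
            name=met.name,
            formula=met.formula,
            charge=met.charge,
            compartment=met.compartment,
        )
        mets[met.id] = m
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for rxn in model.reactions.values():
        r = cobra.Reaction(rxn.id, name=rxn.name)
        r.lower_bound = rxn.lb
        r.upper_bound = rxn.ub
        rxns.append(r)
    cm.add_reactions(rxns)
    for rxn in model.reactions.values():
        cm.reactions.get_by_id(rxn.id).add_metabolites(
            {mets[mid]: c for mid, c in rxn.stoichiometry.items()}
        )
    if model.biomass_reaction_id:
        cm.objective = model.biomass_reaction_id
    return cm


def read_model(
    path: str | Path,
    format: str | None = None,
    *,
    cap: float = DEFAULT_FLUX_CAP,
    biomass_reaction_id: str | None = None,
) -> MetabolicModel:
    """Read an SBML-FBC (``sbml-fbc``) or COBRA JSON (``cobra-json``) model.

    ``format`` is inferred from the suffix when omitted. A model without any
    identifiable biomass/objective reaction raises :class:`ModelError` unless
    ``biomass_reaction_id`` is supplied.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "cobra-json" if path.suffix == ".json" else "sbml-fbc"
    try:
        if format == "cobra-json":
            cm = cobra.io.load_json_model(str(path))
        elif format == "sbml-fbc":
            cm = cobra.io.read_sbml_model(str(path))
        else:
            raise ValueError(f"unknown model format {format!r}")
    except (ValueError, FileNotFoundError):
        raise
    except Exception as exc:  # parse failures from libsbml / json
        raise ModelError(f"cannot parse {path}: {exc}") from exc
    model = from_cobra(cm, cap=cap, biomass_reaction_id=biomass_reaction_id)
    if model.biomass_reaction_id is None:
        raise ModelError(
            f"{path}: no biomass reaction (no FBC objective, no 'biomass' id); "
            "pass biomass_reaction_id explicitly"
        )
    return model


def write_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "cobra-json" if path.suffix == ".json" else "sbml-fbc"
    cm = to_cobra(model)
    if format == "cobra-json":
        cobra.io.save_json_model(cm, str(path), sort=True)
    elif format == "sbml-fbc":
        cobra.io.write_sbml_model(cm, str(path))
    else:
        raise ValueError(f"unknown model format {format!r}")


def read_database(
    path: str | Path, format: str | None = None, *, cap: float = DEFAULT_FLUX_CAP
) -> tuple[dict[str, Reaction], dict[str, Metabolite]]:
    """Read a raw reaction set (stored as a COBRA model file) for curation.

    Returns (reactions, metabolite catalog); pass both to
    :func:`comgapfill.model.curate_database`.
    """
    path = Path(path)
    if format is None:
        format = "cobra-json" if path.suffix == ".json" else "sbml-fbc"
    if format == "cobra-json":
        cm = cobra.io.load_json_model(str(path))
    else:
        cm = cobra.io.read_sbml_model(str(path))
    model = from_cobra(cm, cap=cap)
    model.biomass_reaction_id = None
    for r in model.reactions.values():
        r.is_biomass = False
    return dict(model.reactions), dict(model.metabolites)


def write_database(db: ReactionDatabase, path: str | Path) -> None:
    model = MetabolicModel(
        id="reaction_database",
        metabolites=dict(db.metabolite_catalog),
        reactions={rid: r.copy() for rid, r in db.reactions.items()},
    )
    # catalog may omit uncatalogued species referenced by whitelisted reactions
    for r in model.reactions.values():
        for mid in r.stoichiometry:
            if mid not in model.metabolites:
                model.metabolites[mid] = Metabolite(id=mid)
    write_model(model, path, format="cobra-json")


def read_database_curated(
    path: str | Path, *, cap: float = DEFAULT_FLUX_CAP, provenance: str = ""
) -> ReactionDatabase:
    """Read a database file that is already curated, without re-curation."""
    reactions, catalog = read_database(path, cap=cap)
    return ReactionDatabase(
        reactions=reactions, metabolite_catalog=catalog, provenance=provenance
    )


def write_curation_report(report: dict[str, int], path: str | Path) -> None:
    df = pd.DataFrame(sorted(report.items()), columns=["rule", "count"])
    df.to_csv(path, sep="\t", index=False)


def read_medium(path: str | Path):
    """Read a medium JSON: {"default_policy": ..., "bounds": {base_id: [lb, ub]},
    "member_bounds": {"organism_id::base_id": [lb, ub]}}."""
    from .community import Medium

    with open(path) as fh:
        data = json.load(fh)
    member_bounds = {
        tuple(key.split("::", 1)): tuple(v)
        for key, v in data.get("member_bounds", {}).items()
    }
    return Medium(
        bounds={k: tuple(v) for k, v in data.get("bounds", {}).items()},
        default_policy=data.get("default_policy", "open_secretion_only"),
        member_bounds=member_bounds,
    )


def write_community(cm, path: str | Path) -> None:
    """Serialize a community model (compartments, pool, medium) to JSON.

    This is the lossless staging format between CLI stages; use
    :func:`export_community_cobra` for a flat COBRA-JSON view.
    """
    data = {
        "cap": cm.cap,
        "abundances": cm.abundances,
        "medium": {
            "default_policy": cm.medium.default_policy,
            "bounds": {k: list(v) for k, v in sorted(cm.medium.bounds.items())},
            "member_bounds": {
                f"{org}::{base}": list(v)
                for (org, base), v in sorted(cm.medium.member_bounds.items())
            },
        },
        "pool": {
            base: {
                "pool_id": pm.pool_id,
                "member_links": dict(sorted(pm.member_links.items())),
                "environment_exchange_id": pm.environment_exchange_id,
            }
            for base, pm in sorted(cm.pool.items())
        },
        "members": [
            {
                "organism_id": comp.organism_id,
                "tag": comp.tag,
                "biomass_reaction_id": comp.biomass_reaction_id,
                "min_growth": comp.min_growth,
                "cap": comp.cap,
                "model_reaction_ids": sorted(comp.model_reaction_ids),
                "database_reaction_ids": sorted(comp.database_reaction_ids),
                "ext_metabolites": dict(sorted(comp.ext_metabolites.items())),
                "metabolites": {
                    mid: [m.name, m.formula, m.charge, m.compartment]
                    for mid, m in sorted(comp.metabolites.items())
                },
                "reactions": {
                    rid: {
                        "stoichiometry": dict(sorted(r.stoichiometry.items())),
                        "lb": r.lb,
                        "ub": r.ub,
                        "is_exchange": r.is_exchange,
                        "is_biomass": r.is_biomass,
                    }
                    for rid, r in sorted(comp.reactions.items())
                },
            }
            for comp in cm.members
        ],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)


def read_community(path: str | Path):
    from .community import CommunityModel, Medium, OrganismCompartment, PoolMetabolite

    with open(path) as fh:
        data = json.load(fh)
    medium = Medium(
        bounds={k: tuple(v) for k, v in data["medium"]["bounds"].items()},
        default_policy=data["medium"]["default_policy"],
        member_bounds={
            tuple(key.split("::", 1)): tuple(v)
            for key, v in data["medium"].get("member_bounds", {}).items()
        },
    )
    members = []
    for m in data["members"]:
        metabolites = {
            mid: Metabolite(
                id=mid, name=vals[0] or "", formula=vals[1], charge=vals[2],
                compartment=vals[3],
            )
            for mid, vals in m["metabolites"].items()
        }
        reactions = {
            rid: Reaction(
                id=rid,
                stoichiometry={k: float(c) for k, c in rv["stoichiometry"].items()},
                lb=rv["lb"],
                ub=rv["ub"],
                is_exchange=rv["is_exchange"],
                is_biomass=rv["is_biomass"],
            )
            for rid, rv in m["reactions"].items()
        }
        members.append(
            OrganismCompartment(
                organism_id=m["organism_id"],
                tag=m["tag"],
                reactions=reactions,
                metabolites=metabolites,
                model_reaction_ids=set(m["model_reaction_ids"]),
                database_reaction_ids=set(m["database_reaction_ids"]),
                ext_metabolites=dict(m["ext_metabolites"]),
                biomass_reaction_id=m["biomass_reaction_id"],
                min_growth=m["min_growth"],
                cap=m["cap"],
            )
        )
    pool = {
        base: PoolMetabolite(
            base_id=base,
            pool_id=pv["pool_id"],
            member_links=dict(pv["member_links"]),
            environment_exchange_id=pv["environment_exchange_id"],
        )
        for base, pv in data["pool"].items()
    }
    cm = CommunityModel(
        members=members, pool=pool, medium=medium,
        abundances=data.get("abundances"), cap=data["cap"],
    )
    cm.validate()
    return cm


def export_community_cobra(cm, path: str | Path) -> None:
    """Flat COBRA-JSON view of the community (one model, tagged compartments)."""
    model = MetabolicModel(id="community")
    for comp in cm.members:
        model.metabolites.update(comp.metabolites)
        for rid, r in comp.reactions.items():
            model.reactions[rid] = r.copy()
    for base, pm in sorted(cm.pool.items()):
        model.metabolites[pm.pool_id] = Metabolite(
            id=pm.pool_id, compartment="pool"
        )
        for comp in cm.members:
            if comp.organism_id not in pm.member_links:
                continue
            tid = pm.member_links[comp.organism_id]
            lo, hi = cm.medium.member_bounds.get(
                (comp.organism_id, base), (-cm.cap, cm.cap)
            )
            model.reactions[tid] = Reaction(
                id=tid,
                stoichiometry={
                    comp.ext_metabolites[base]: -1.0,
                    pm.pool_id: 1.0,
                },
                lb=lo, ub=hi,
            )
        lo, hi = cm.medium.environment_bounds(base, cm.cap)
        model.reactions[pm.environment_exchange_id] = Reaction(
            id=pm.environment_exchange_id,
            stoichiometry={pm.pool_id: -1.0},
            lb=lo, ub=hi, is_exchange=True,
        )
    model.biomass_reaction_id = cm.members[0].biomass_reaction_id
    write_model(model, path, format="cobra-json")


def write_medium(medium, path: str | Path) -> None:
    data = {
        "default_policy": medium.default_policy,
        "bounds": {k: list(v) for k, v in sorted(medium.bounds.items())},
        "member_bounds": {
            f"{org}::{base}": list(v)
            for (org, base), v in sorted(medium.member_bounds.items())
        },
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)
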