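"""Core containers for metabolic networks and the reaction database.

The containers are deliberately lightweight (plain dataclasses keyed by
string ids) so that community assembly can namespace and recombine them
freely; conversion to/from COBRApy objects lives in :mod:`comgapfill.io`.

Fluxes are in mmol·gDW⁻¹·h⁻¹ (or any consistent unit system); unbounded
bounds are represented by a finite global cap (``DEFAULT_FLUX_CAP``),
the standard COBRA ±1000 convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

DEFAULT_FLUX_CAP = 1000.0

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised when an elemental formula string cannot be parsed."""


class ModelError(ValueError):
    """Raised for referential-integrity or contract violations in a model."""


@dataclass(frozen=True)
class Metabolite:
    """A chemical species in one compartment.

    ``formula`` and ``charge`` may be absent (None); mass-balance checks on
    reactions touching such a species return ``"undetermined"``.
    """

    id: str
    name: str = ""
    formula: str | None = None
    charge: int | None = None
    compartment: str = "c"

    @property
    def elements(self) -> dict[str, int] | None:
        if self.formula is None:
            return None
        return parse_formula(self.formula)


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds.

    ``stoichiometry`` maps metabolite id -> coefficient (negative =
    consumed). Exchange reactions touch exactly one metabolite and cross
    the system boundary; at most one reaction per model is the biomass
    objective.
    """

    id: str
    stoichiometry: dict[str, float]
    lb: float = -DEFAULT_FLUX_CAP
    ub: float = DEFAULT_FLUX_CAP
    is_exchange: bool = False
    is_biomass: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if self.lb > self.ub:
            raise ModelError(f"reaction {self.id}: lb {self.lb} > ub {self.ub}")
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id}: empty stoichiometry")
        if self.is_exchange and len(self.stoichiometry) != 1:
            raise ModelError(
                f"exchange reaction {self.id} must touch exactly one metabolite"
            )

    def copy(self, **changes) -> "Reaction":
        r = replace(self, stoichiometry=dict(self.stoichiometry))
        for k, v in changes.items():
            setattr(r, k, v)
        return r


@dataclass
class MetabolicModel:
    """One organism's network: metabolites, bounded reactions, a biomass reaction."""

    id: str
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    biomass_reaction_id: str | None = None

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for met in rxn.stoichiometry:
                if met not in self.metabolites:
                    raise ModelError(
                        f"reaction {rxn.id} references undeclared metabolite {met}"
                    )
        if self.biomass_reaction_id is not None:
            if self.biomass_reaction_id not in self.reactions:
                raise ModelError(
                    f"biomass reaction {self.biomass_reaction_id} not in model {self.id}"
                )

    @property
    def biomass_reaction(self) -> Reaction:
        if self.biomass_reaction_id is None:
            raise ModelError(f"model {self.id} has no biomass reaction")
        return self.reactions[self.biomass_reaction_id]

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=dict(self.metabolites),
            reactions={rid: r.copy() for rid, r in self.reactions.items()},
            biomass_reaction_id=self.biomass_reaction_id,
        )


@dataclass
class ReactionDatabase:
    """Curated universal reaction set used as the gap-filling candidate pool.

    Invariants (enforced by :func:`curate_database`): no exchange reactions,
    no biomass reactions, every retained reaction mass/charge balanced
    unless whitelisted.
    """

    reactions: dict[str, Reaction] = field(default_factory=dict)
    metabolite_catalog: dict[str, Metabolite] = field(default_factory=dict)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.reactions)


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style elemental formula into element -> count.

    Pseudo-elements ("R", "X") are accepted as opaque one- or two-letter
    symbols; an omitted count means 1. Repeated symbols accumulate.
    """
    if not formula:
        raise FormulaError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise FormulaError(
                f"unparseable token at position {pos} in formula {formula!r}"
            )
        element, digits = m.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(formula):
        raise FormulaError(
            f"unparseable token at position {pos} in formula {formula!r}"
        )
    return counts


def check_mass_balance(
    reaction: Reaction, catalog: dict[str, Metabolite]
) -> str:
    """Verdict on elemental and charge balance: 'balanced' | 'imbalanced' | 'undetermined'.

    Balanced iff, for every element and for charge, the stoichiometry-weighted
    sums over all participants are exactly zero. Undetermined iff any
    participant lacks a formula (a missing charge is treated as 0).
    Exchange reactions are by construction unbalanced and must not be passed.
    """
    if reaction.is_exchange:
        raise ModelError(f"{reaction.id}: mass balance undefined for exchanges")
    totals: dict[str, float] = {}
    charge = 0.0
    for met_id, coeff in reaction.stoichiometry.items():
        met = catalog.get(met_id)
        if met is None or met.formula is None:
            return "undetermined"
        for element, count in met.elements.items():
            totals[element] = totals.get(element, 0.0) + coeff * count
        charge += coeff * (met.charge or 0)
    if any(abs(t) > 1e-9 for t in totals.values()) or abs(charge) > 1e-9:
        return "imbalanced"
    return "balanced"


def curate_database(
    raw: dict[str, Reaction] | list[Reaction],
    catalog: dict[str, Metabolite],
    exclusions: list[str] | None = None,
    biomass_patterns: list[str] | None = None,
    *,
    cap: float = DEFAULT_FLUX_CAP,
    keep_undetermined: bool = False,
    whitelist: list[str] | None = None,
    provenance: str = "",
) -> tuple[ReactionDatabase, dict[str, int]]:
    """Build a curated :class:`ReactionDatabase` from a raw reaction set.

    Removal rules, in order: biomass equations (explicit flag or
    case-insensitive id/name pattern match, default pattern ``"biomass"``),
    user exclusion list (stands in for "eukaryote-only" reactions, for which
    no algorithmic rule exists), exchange reactions, and reactions that are
    mass/charge imbalanced or of undetermined balance (the latter retained
    when ``keep_undetermined``). Survivors are made reversible with bounds
    (-cap, +cap): candidate directionality is decided later by FVA.

    Returns the database and a curation report of counts removed per rule.
    """
    if isinstance(raw, list):
        raw = {r.id: r for r in raw}
    if biomass_patterns is None:
        biomass_patterns = ["biomass"]
    exclusions_set = set(exclusions or [])
    whitelist_set = set(whitelist or [])
    patterns = [p.lower() for p in biomass_patterns]

    report = {
        "input": len(raw),
        "removed_biomass": 0,
        "removed_excluded": 0,
        "removed_exchange": 0,
        "removed_imbalanced": 0,
        "removed_undetermined": 0,
        "retained": 0,
    }
    kept: dict[str, Reaction] = {}
    for rid in sorted(raw):
        rxn = raw[rid]
        text = f"{rxn.id} {rxn.name}".lower()
        if rxn.is_biomass or any(p in text for p in patterns):
            report["removed_biomass"] += 1
            continue
        if rid in exclusions_set:
            report["removed_excluded"] += 1
            continue
        if rxn.is_exchange:
            report["removed_exchange"] += 1
            continue
        if rid not in whitelist_set:
            verdict = check_mass_balance(rxn, catalog)
            if verdict == "imbalanced":
                report["removed_imbalanced"] += 1
                continue
            if verdict == "undetermined" and not keep_undetermined:
                report["removed_undetermined"] += 1
                continue
        kept[rid] = rxn.copy(lb=-cap, ub=cap)
    report["retained"] = len(kept)

    used_mets = {m for r in kept.values() for m in r.stoichiometry}
    db_catalog = {mid: catalog[mid] for mid in sorted(used_mets) if mid in catalog}
    db = ReactionDatabase(
        reactions=kept, metabolite_catalog=db_catalog, provenance=provenance
    )
    return db, report
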