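"""Flux variability analysis over candidate database reactions.

Run per organism compartment before the MILP is formulated: every database
candidate gets LP-exact minimum and maximum fluxes, which then replace its
reversible (-cap, +cap) bounds; candidates whose range is identically zero
are deleted. The relaxation used (biomass floor dropped to zero, all pool
transfers fully open) over-approximates every community-feasible flux
assignment for the compartment, which is what makes the pruning sound: no
reaction that could carry flux in any community optimum is removed, and no
surviving bound cuts off such a flux.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._linalg import InfeasibleError
from .community import Medium, OrganismCompartment, compartment_system

ZERO_TOL = 1e-6


@dataclass
class FVAResult:
    """Per-reaction flux ranges plus a description of the relaxation used."""

    ranges: dict[str, tuple[float, float]]
    context: str = ""

    def __post_init__(self) -> None:
        for rid, (lo, hi) in self.ranges.items():
            if lo > hi + 1e-9:
                raise ValueError(f"{rid}: FVA min {lo} > max {hi}")

    def to_frame(self, zero_tol: float = ZERO_TOL) -> pd.DataFrame:
        rows = [
            {
                "reaction_id": rid,
                "min": lo,
                "max": hi,
                "pruned": abs(lo) <= zero_tol and abs(hi) <= zero_tol,
            }
            for rid, (lo, hi) in sorted(self.ranges.items())
        ]
        return pd.DataFrame(rows, columns=["reaction_id", "min", "max", "pruned"])


def run_compartment_fva(
    comp: OrganismCompartment,
    medium: Medium | None = None,
    *,
    relax_growth: bool = True,
    open_transfers: bool = True,
    reaction_ids: list[str] | None = None,
) -> FVAResult:
    """LP-exact flux ranges for the compartment's database candidates.

    With the defaults the compartment is relaxed to the soundness
    over-approximation (growth floor 0, transfers open); ``relax_growth=False``
    enforces the member's growth floor and raises :class:`InfeasibleError`
    for models that cannot yet grow (gapped models typically cannot).
    """
    sys = compartment_system(
        comp,
        open_transfers=open_transfers,
        medium=medium,
        relax_growth=relax_growth,
    )
    if not sys.feasible():
        raise InfeasibleError(
            f"compartment {comp.organism_id}: infeasible under relaxation "
            f"(relax_growth={relax_growth}); the growth floor "
            f"{comp.min_growth} cannot be met before gap-filling"
        )
    targets = sorted(reaction_ids or comp.database_reaction_ids)
    ranges = {rid: sys.flux_range(rid) for rid in targets}
    context = (
        f"relax_growth={relax_growth}, open_transfers={open_transfers}, "
        f"cap={comp.cap}"
    )
    return FVAResult(ranges=ranges, context=context)


def prune_and_tighten(
    comp: OrganismCompartment,
    fva: FVAResult,
    zero_tol: float = ZERO_TOL,
) -> OrganismCompartment:
    """Delete zero-range candidates and tighten the rest to their FVA range.

    Surviving bounds are rounded outward by ``zero_tol`` so that solver
    tolerance in the FVA LPs cannot render the MILP spuriously infeasible.
    Model reactions are untouched.
    """
    missing = comp.database_reaction_ids - set(fva.ranges)
    if missing:
        raise ValueError(f"FVA result missing candidates: {sorted(missing)[:5]}")
    out = comp.copy()
    for rid in sorted(comp.database_reaction_ids):
        lo, hi = fva.ranges[rid]
        if abs(lo) <= zero_tol and abs(hi) <= zero_tol:
            del out.reactions[rid]
            out.database_reaction_ids.discard(rid)
        else:
            out.reactions[rid].lb = lo - zero_tol
            out.reactions[rid].ub = hi + zero_tol
    return out


def reduce_community(cm, *, zero_tol: float = ZERO_TOL, medium=None):
    """FVA-prune every member of a community; returns (community, report).

    The report is one row per member with candidate counts before/after.
    """
    from dataclasses import replace

    new_members = []
    rows = []
    for comp in cm.members:
        fva = run_compartment_fva(comp, medium or cm.medium)
        pruned = prune_and_tighten(comp, fva, zero_tol)
        new_members.append(pruned)
        rows.append(
            {
                "organism_id": comp.organism_id,
                "candidates_before": len(comp.database_reaction_ids),
                "candidates_after": len(pruned.database_reaction_ids),
            }
        )
    return replace(cm, members=new_members), pd.DataFrame(rows)
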