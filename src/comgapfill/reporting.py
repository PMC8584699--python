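"""Post-solution analysis: cross-feeding, added-reaction frequencies, quality flags.

A cross-feeding edge exists, within one solution, when one member's pool
transfer flux for a metabolite is strictly positive (secretion) and another
member's is strictly negative (uptake), both above tolerance; concurrent
environment involvement (e.g. shared oxygen) does not cancel an edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import CommunityModel
from .gapfill import EnumerationResult, GapfillSolution

EDGE_TOL = 1e-6


@dataclass
class ExchangeReport:
    """Tidy transfer/environment fluxes plus derived cross-feeding edges."""

    fluxes: pd.DataFrame  # solution_rank, metabolite, member, flux
    edges: pd.DataFrame  # solution_rank, producer, consumer, metabolite, magnitude
    consensus_edges: pd.DataFrame  # producer, consumer, metabolite, frequency


def extract_exchanges(
    solutions: EnumerationResult | list[GapfillSolution],
    community: CommunityModel,
    *,
    tol: float = EDGE_TOL,
) -> ExchangeReport:
    """Exchange fluxes and cross-feeding edges for every enumerated solution.

    The consensus table keeps edges present in at least half the solutions.
    """
    sols = solutions.solutions if isinstance(solutions, EnumerationResult) else solutions
    if not sols:
        raise ValueError("no solutions to report")
    flux_rows, edge_rows = [], []
    for rank, sol in enumerate(sols, start=1):
        for base in sorted(community.pool):
            pm = community.pool[base]
            member_flux = {}
            for org, tid in sorted(pm.member_links.items()):
                v = sol.fluxes.get(tid, 0.0)
                member_flux[org] = v
                flux_rows.append(
                    {"solution_rank": rank, "metabolite": base, "member": org,
                     "flux": v}
                )
            flux_rows.append(
                {"solution_rank": rank, "metabolite": base,
                 "member": "environment",
                 "flux": sol.fluxes.get(pm.environment_exchange_id, 0.0)}
            )
            producers = [(o, v) for o, v in member_flux.items() if v > tol]
            consumers = [(o, v) for o, v in member_flux.items() if v < -tol]
            for po, pv in producers:
                for co, cv in consumers:
                    edge_rows.append(
                        {"solution_rank": rank, "producer": po, "consumer": co,
                         "metabolite": base, "magnitude": min(pv, -cv)}
                    )
    fluxes = pd.DataFrame(
        flux_rows, columns=["solution_rank", "metabolite", "member", "flux"]
    )
    edges = pd.DataFrame(
        edge_rows,
        columns=["solution_rank", "producer", "consumer", "metabolite", "magnitude"],
    )
    if len(edges):
        freq = (
            edges.groupby(["producer", "consumer", "metabolite"])["solution_rank"]
            .nunique()
            .div(len(sols))
            .rename("frequency")
            .reset_index()
        )
        consensus = freq[freq["frequency"] >= 0.5].reset_index(drop=True)
    else:
        consensus = pd.DataFrame(
            columns=["producer", "consumer", "metabolite", "frequency"]
        )
    return ExchangeReport(fluxes=fluxes, edges=edges, consensus_edges=consensus)


def summarize_additions(
    solutions: EnumerationResult | list[GapfillSolution],
    community: CommunityModel | None = None,
) -> pd.DataFrame:
    """Fraction of solutions containing each (member, database reaction)."""
    sols = solutions.solutions if isinstance(solutions, EnumerationResult) else solutions
    if not sols:
        raise ValueError("no solutions to summarize")
    counts: dict[tuple[str, str], int] = {}
    for sol in sols:
        for org, rid in sol.support:
            counts[(org, rid)] = counts.get((org, rid), 0) + 1
    rows = [
        {"member": org, "reaction": rid, "frequency": c / len(sols)}
        for (org, rid), c in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["member", "reaction", "frequency"])
    return df.sort_values(
        ["frequency", "member", "reaction"], ascending=[False, True, True]
    ).reset_index(drop=True)


@dataclass
class QualityFlags:
    """Heuristic red flags on one solution's flux vector."""

    near_bound: list[str]
    cycle_pairs: list[tuple[str, str]]
    thresholds: dict = field(default_factory=dict)

    @property
    def trust_penalty(self) -> int:
        return len(self.near_bound) + len(self.cycle_pairs)


def _normalized_stoichiometry(stoich: dict[str, float]) -> tuple:
    items = sorted(stoich.items())
    norm = np.linalg.norm([c for _, c in items])
    sign = 1.0 if items[0][1] > 0 else -1.0
    return tuple((m, round(sign * c / norm, 9)) for m, c in items), sign


def flag_quality(
    solution: GapfillSolution,
    community: CommunityModel,
    *,
    near_bound_fraction: float = 0.9,
    abs_threshold: float = 100.0,
) -> QualityFlags:
    """Flag unrealistically high fluxes and paired-reaction cycles.

    ``near_bound``: reactions with |v| at or above ``near_bound_fraction`` of
    their own bound and above ``abs_threshold`` (candidate thermodynamic
    artifacts, typically fluxes near the global cap). ``cycle_pairs``:
    reaction pairs whose stoichiometries are proportional (same or opposite
    direction) and whose fluxes both exceed ``abs_threshold`` with a
    cancelling net effect — the pairwise signature of an infeasible cycle.
    """
    if not solution.fluxes:
        raise ValueError("solution carries no fluxes")
    near = []
    candidates = []
    for comp in community.members:
        for rid in sorted(comp.reactions):
            v = solution.fluxes.get(rid)
            if v is None:
                continue
            rxn = comp.reactions[rid]
            bound = max(abs(rxn.lb), abs(rxn.ub))
            if (bound > 0 and abs(v) >= near_bound_fraction * bound) or (
                abs(v) >= abs_threshold
            ):
                near.append(rid)
            if abs(v) >= abs_threshold:
                candidates.append((rid, rxn, v, comp.tag))
    cycles = []
    for i in range(len(candidates)):
        rid1, r1, v1, tag1 = candidates[i]
        key1, sign1 = _normalized_stoichiometry(r1.stoichiometry)
        for j in range(i + 1, len(candidates)):
            rid2, r2, v2, tag2 = candidates[j]
            if tag1 != tag2:
                continue
            key2, sign2 = _normalized_stoichiometry(r2.stoichiometry)
            if key1 != key2:
                continue
            # net flux through the shared stoichiometry cancels when the
            # direction-corrected fluxes oppose each other
            if (sign1 * v1) * (sign2 * v2) < 0:
                cycles.append((rid1, rid2))
    return QualityFlags(
        near_bound=sorted(near),
        cycle_pairs=sorted(cycles),
        thresholds={
            "near_bound_fraction": near_bound_fraction,
            "abs_threshold": abs_threshold,
        },
    )


def crossfeeding_dot(report: ExchangeReport) -> str:
    """GraphViz DOT export of the consensus cross-feeding graph."""
    lines = ["digraph crossfeeding {"]
    for _, row in report.consensus_edges.iterrows():
        lines.append(
            f'  "{row.producer}" -> "{row.consumer}" '
            f'[label="{row.metabolite} ({row.frequency:.0%})"];'
        )
    lines.append("}")
    return "\n".join(lines)
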