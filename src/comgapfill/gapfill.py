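"""The community gap-filling MILP and enumeration of alternative optima.

Objective: minimize the total number of database reactions switched on
across all member compartments,

    min  sum_n sum_{j in J_Database^n} y_j^n

subject to per-compartment steady state (S^n v^n = 0), model-reaction
bounds, binary-gated candidate bounds (y lb <= v <= y ub), per-member
biomass floors (v_Biomass^n >= v_min^n), pool balance
(-v_ex^c + sum_n w_n v_ex^n = 0), and y binary. Solved with HiGHS via
scipy; alternative optima are enumerated with solver-agnostic integer cuts
on the binary support (sum_{support} y <= |support| - 1), so results are
reproducible across free solvers.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from ._linalg import InfeasibleError, LinearSystem
from .community import CommunityModel, community_system
from .model import MetabolicModel, ModelError, ReactionDatabase, Metabolite
from dataclasses import replace as _dc_replace

FEASIBILITY_TOL = 1e-9
ZERO_FLUX_TOL = 1e-6

Support = frozenset  # of (organism_id, database reaction base id)


@dataclass
class GapfillProblem:
    community: CommunityModel
    growth_floors: dict[str, float]
    weighted: bool = False
    system: LinearSystem = field(init=False, repr=False)
    binaries: list[tuple[str, str, str]] = field(init=False, repr=False)
    # (organism_id, base reaction id, namespaced reaction id)

    def __post_init__(self) -> None:
        for org, floor in self.growth_floors.items():
            if floor <= 0:
                raise ModelError(
                    f"growth floor for {org} must be positive (got {floor}); "
                    "a zero floor would make gap-filling vacuous"
                )
        if self.weighted and self.community.abundances is None:
            raise ModelError("weighted=True requires community abundances")
        weights = self.community.abundances if self.weighted else None
        self.system = community_system(
            self.community, growth_floors=self.growth_floors, weights=weights
        )
        self.binaries = []
        for comp in self.community.members:
            suffix = f"__{comp.tag}"
            for rid in sorted(comp.database_reaction_ids):
                base = rid[: -len(suffix)] if rid.endswith(suffix) else rid
                self.binaries.append((comp.organism_id, base, rid))

    @property
    def n_binaries(self) -> int:
        return len(self.binaries)

    def support_bounds(self, support: Support) -> dict[str, tuple[float, float]]:
        """Flux-bound overrides fixing a binary support: active candidates get
        their (possibly FVA-tightened) bounds, inactive ones are clamped to 0."""
        overrides = {}
        active = set(support)
        for org, base, rid in self.binaries:
            if (org, base) in active:
                j = self.system.var_index[rid]
                overrides[rid] = (self.system.lb[j], self.system.ub[j])
            else:
                overrides[rid] = (0.0, 0.0)
        return overrides


@dataclass
class GapfillSolution:
    status: str  # optimal | infeasible | time_limit
    objective_value: int | None
    added: dict[str, list[str]]  # organism_id -> base reaction ids
    fluxes: dict[str, float]
    solver_meta: dict = field(default_factory=dict)

    @property
    def support(self) -> Support:
        return frozenset(
            (org, rid) for org, rids in self.added.items() for rid in rids
        )


@dataclass
class EnumerationResult:
    solutions: list[GapfillSolution]
    exhaustive_at_optimum: bool
    cuts_applied: int

    @property
    def best(self) -> GapfillSolution:
        return self.solutions[0]


def formulate(
    community: CommunityModel,
    growth_floors: dict[str, float] | None = None,
    weighted: bool = False,
) -> GapfillProblem:
    """Build the MILP. Floors default to each member's ``min_growth``."""
    if growth_floors is None:
        growth_floors = {c.organism_id: c.min_growth for c in community.members}
    return GapfillProblem(community, growth_floors, weighted)


def _milp_arrays(problem: GapfillProblem, cuts: list[Support]):
    sys = problem.system
    nv = sys.n_vars
    nb = problem.n_binaries
    n = nv + nb

    c = np.concatenate([np.zeros(nv), np.ones(nb)])
    integrality = np.concatenate([np.zeros(nv), np.ones(nb)])

    # flux bounds; candidate flux boxes widened to include 0 (gating closes them)
    lb = np.concatenate([sys.lb.copy(), np.zeros(nb)])
    ub = np.concatenate([sys.ub.copy(), np.ones(nb)])
    constraints = []

    A_eq = sparse.hstack([sys.A, sparse.csr_matrix((sys.A.shape[0], nb))])
    constraints.append(LinearConstraint(A_eq, 0.0, 0.0))

    rows, cols, vals = [], [], []
    g_lb, g_ub = [], []
    for k, (_, _, rid) in enumerate(problem.binaries):
        j = sys.var_index[rid]
        lo, hi = sys.lb[j], sys.ub[j]
        lb[j] = min(lo, 0.0)
        ub[j] = max(hi, 0.0)
        #  v - ub*y <= 0
        rows += [2 * k, 2 * k]
        cols += [j, nv + k]
        vals += [1.0, -hi]
        g_lb.append(-np.inf)
        g_ub.append(0.0)
        #  v - lb*y >= 0
        rows += [2 * k + 1, 2 * k + 1]
        cols += [j, nv + k]
        vals += [1.0, -lo]
        g_lb.append(0.0)
        g_ub.append(np.inf)
    if nb:
        G = sparse.csr_matrix((vals, (rows, cols)), shape=(2 * nb, n))
        constraints.append(LinearConstraint(G, np.array(g_lb), np.array(g_ub)))

    key = {(org, base): k for k, (org, base, _) in enumerate(problem.binaries)}
    for cut in cuts:
        row = np.zeros(n)
        for org_base in cut:
            row[nv + key[org_base]] = 1.0
        constraints.append(LinearConstraint(row, -np.inf, len(cut) - 1))

    return c, integrality, Bounds(lb, ub), constraints


def _diagnose_infeasibility(problem: GapfillProblem) -> list[str]:
    """Which members' floors fail even with the full database switched on
    and every other member's floor relaxed to zero."""
    full = Support((org, base) for org, base, _ in problem.binaries)
    failing = []
    for comp in problem.community.members:
        floors = {
            c.organism_id: (
                problem.growth_floors[c.organism_id]
                if c.organism_id == comp.organism_id
                else 0.0
            )
            for c in problem.community.members
        }
        weights = problem.community.abundances if problem.weighted else None
        sys = community_system(
            problem.community, growth_floors=floors, weights=weights
        )
        # floor of 0 keeps the biomass lb at max(lb, 0); that is the relaxation
        sys = sys.with_bounds(problem.support_bounds(full))
        if not sys.feasible():
            failing.append(comp.organism_id)
    return failing


def _extract_solution(
    problem: GapfillProblem, support: Support, meta: dict
) -> GapfillSolution:
    """Fix the support, re-solve the LP (minimum total flux), verify."""
    sys = problem.system.with_bounds(problem.support_bounds(support))
    fluxes_vec = sys.min_total_flux_solution()
    fluxes = {vid: float(v) for vid, v in zip(sys.var_ids, fluxes_vec)}

    residual = np.abs(sys.A @ fluxes_vec)
    if residual.size and residual.max() > 1e-6:
        raise RuntimeError(
            f"steady-state residual {residual.max():.2e} exceeds tolerance"
        )
    added: dict[str, list[str]] = {c.organism_id: [] for c in problem.community.members}
    for org, base in sorted(support):
        added[org].append(base)
    return GapfillSolution(
        status="optimal",
        objective_value=len(support),
        added=added,
        fluxes=fluxes,
        solver_meta=meta,
    )


def solve(
    problem: GapfillProblem,
    *,
    time_limit: float | None = None,
    mip_gap: float = 0.0,
    cuts: list[Support] | None = None,
) -> GapfillSolution:
    """Solve the MILP to proven optimality (default mip_gap 0).

    The binary support is rounded at 0.5 and re-verified by fixing the
    binaries and re-solving the LP; the reported flux vector is the
    minimum-total-flux point of that LP (deterministic). On infeasibility
    the solution carries a hint naming members whose floor is unreachable
    even with the full database.
    """
    cuts = cuts or []
    c, integrality, bounds, constraints = _milp_arrays(problem, cuts)
    options = {"mip_rel_gap": mip_gap, "presolve": True}
    if time_limit is not None:
        options["time_limit"] = time_limit
    t0 = time.perf_counter()
    res = milp(
        c,
        constraints=constraints,
        integrality=integrality,
        bounds=bounds,
        options=options,
    )
    runtime = time.perf_counter() - t0
    meta = {"runtime_s": runtime, "mip_gap": mip_gap, "solver": "highs"}
    if res.status == 2:
        # with cuts in place infeasibility just means enumeration is exhausted
        hint = _diagnose_infeasibility(problem) if not cuts else []
        return GapfillSolution(
            status="infeasible",
            objective_value=None,
            added={},
            fluxes={},
            solver_meta={**meta, "infeasible_members": hint},
        )
    if res.x is None:
        status = "time_limit" if res.status == 1 else "infeasible"
        return GapfillSolution(
            status=status, objective_value=None, added={}, fluxes={}, solver_meta=meta
        )
    nv = problem.system.n_vars
    y = res.x[nv:]
    support = Support(
        (org, base)
        for (org, base, _), yk in zip(problem.binaries, y)
        if yk > 0.5
    )
    solution = _extract_solution(problem, support, meta)
    if res.status == 1:
        solution.status = "time_limit"
    return solution


def enumerate_alternatives(
    problem: GapfillProblem,
    k: int = 10,
    *,
    time_limit: float | None = None,
    allow_suboptimal: bool = True,
) -> EnumerationResult:
    """Enumerate up to ``k`` solutions by iterative integer cuts.

    Each found binary support is excluded by sum_{support} y <= |support|-1
    and the MILP re-solved, so solutions are distinct supports in
    non-decreasing objective order. With ``allow_suboptimal`` the list may
    run past the optimum ("k best"); otherwise enumeration stops at the
    first strictly worse objective and ``exhaustive_at_optimum`` is set.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    solutions: list[GapfillSolution] = []
    cuts: list[Support] = []
    exhaustive = False
    best: int | None = None
    deadline = time.perf_counter() + time_limit if time_limit is not None else None
    while len(solutions) < k:
        remaining = None
        if deadline is not None:
            remaining = max(deadline - time.perf_counter(), 0.1)
        sol = solve(problem, time_limit=remaining, cuts=cuts)
        if sol.status == "infeasible":
            exhaustive = True
            break
        if sol.status == "time_limit":
            solutions.append(sol) if sol.objective_value is not None else None
            break
        if best is None:
            best = sol.objective_value
        if sol.objective_value > best:
            exhaustive = True
            if not allow_suboptimal:
                break
        solutions.append(sol)
        cuts.append(sol.support)
    return EnumerationResult(
        solutions=solutions, exhaustive_at_optimum=exhaustive, cuts_applied=len(cuts)
    )


def apply_and_verify(
    model: MetabolicModel,
    solution: GapfillSolution,
    db: ReactionDatabase,
    community: CommunityModel,
) -> tuple[MetabolicModel, float]:
    """Materialize a member's added reactions and verify growth in context.

    The standalone gap-filled model gets the database's original reversible
    bounds back (FVA-tightened bounds are context-dependent artifacts of the
    reduction and are not exported). The returned growth rate is the
    member's FBA maximum in the community context with every member's
    support fixed, which must reach its floor.
    """
    org = model.id
    added = solution.added.get(org, [])
    filled = model.copy()
    for base in added:
        if base not in db.reactions:
            raise ModelError(f"solution adds unknown database reaction {base}")
        rxn = db.reactions[base].copy()
        for mid in rxn.stoichiometry:
            if mid not in filled.metabolites:
                proto = db.metabolite_catalog.get(mid, Metabolite(id=mid))
                filled.metabolites[mid] = _dc_replace(proto, id=mid)
        filled.reactions[base] = rxn
    filled.validate()

    problem = formulate(
        community,
        growth_floors={c.organism_id: c.min_growth for c in community.members},
    )
    sys = problem.system.with_bounds(problem.support_bounds(solution.support))
    comp = community.member(org)
    try:
        growth, _ = sys.optimize({comp.biomass_reaction_id: 1.0}, "max")
    except InfeasibleError as exc:
        raise RuntimeError(
            f"verification LP infeasible for {org}: bound restoration or "
            f"tolerance bug"
        ) from exc
    if growth < comp.min_growth - 1e-6:
        raise RuntimeError(
            f"verification FBA growth {growth:.6g} below floor "
            f"{comp.min_growth} for {org}"
        )
    return filled, float(growth)
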