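"""Sparse steady-state systems and LP solves shared by FVA, FBA and the MILP.

All optimization goes through scipy's HiGHS interfaces, which are
deterministic for fixed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog


class InfeasibleError(RuntimeError):
    pass


@dataclass
class LinearSystem:
    """Steady-state system A x = 0 with box bounds, over named flux variables."""

    var_ids: list[str]
    lb: np.ndarray
    ub: np.ndarray
    A: sparse.csr_matrix
    row_ids: list[str]
    var_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.var_index = {v: i for i, v in enumerate(self.var_ids)}

    @property
    def n_vars(self) -> int:
        return len(self.var_ids)

    def with_bounds(self, overrides: dict[str, tuple[float, float]]) -> "LinearSystem":
        lb = self.lb.copy()
        ub = self.ub.copy()
        for vid, (lo, hi) in overrides.items():
            j = self.var_index[vid]
            lb[j], ub[j] = lo, hi
        return LinearSystem(self.var_ids, lb, ub, self.A, self.row_ids)

    def optimize(
        self, objective: dict[str, float], sense: str = "max"
    ) -> tuple[float, np.ndarray]:
        """Optimize a linear objective over the steady-state polytope.

        Raises :class:`InfeasibleError` when the polytope is empty.
        """
        c = np.zeros(self.n_vars)
        for vid, coeff in objective.items():
            c[self.var_index[vid]] = coeff
        sign = -1.0 if sense == "max" else 1.0
        res = linprog(
            sign * c,
            A_eq=self.A,
            b_eq=np.zeros(self.A.shape[0]),
            bounds=np.column_stack([self.lb, self.ub]),
            method="highs",
        )
        if res.status == 2:
            raise InfeasibleError("LP infeasible")
        if not res.success:
            raise RuntimeError(f"LP failed: {res.message}")
        return sign * res.fun, res.x

    def feasible(self) -> bool:
        try:
            self.optimize({}, "min")
            return True
        except InfeasibleError:
            return False

    def min_total_flux_solution(self) -> np.ndarray:
        """A feasible point minimizing sum |x| (pFBA-style, deterministic).

        Splits each flux into positive and negative parts; ties among
        alternate optima are resolved by HiGHS deterministically.
        """
        n = self.n_vars
        # x = p - q, p,q >= 0, p <= max(ub,0), q <= max(-lb,0); A(p-q)=0
        A2 = sparse.hstack([self.A, -self.A]).tocsr()
        lb2 = np.zeros(2 * n)
        ub2 = np.concatenate([np.maximum(self.ub, 0.0), np.maximum(-self.lb, 0.0)])
        # keep the original box: p - q in [lb, ub]
        eye = sparse.eye(n, format="csr")
        box = sparse.hstack([eye, -eye]).tocsr()
        res = linprog(
            np.ones(2 * n),
            A_eq=A2,
            b_eq=np.zeros(A2.shape[0]),
            A_ub=sparse.vstack([box, -box]).tocsr(),
            b_ub=np.concatenate([self.ub, -self.lb]),
            bounds=np.column_stack([lb2, ub2]),
            method="highs",
        )
        if res.status == 2:
            raise InfeasibleError("LP infeasible")
        if not res.success:
            raise RuntimeError(f"LP failed: {res.message}")
        return res.x[:n] - res.x[n:]

    def flux_range(self, var_id: str) -> tuple[float, float]:
        lo, _ = self.optimize({var_id: 1.0}, "min")
        hi, _ = self.optimize({var_id: 1.0}, "max")
        return lo, hi
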