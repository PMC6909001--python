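"""Thin linear/mixed-integer program builder over scipy's HiGHS interface.

Variables are referenced by name. Pure LPs go through
``scipy.optimize.linprog`` (which distinguishes infeasible from unbounded);
problems with integer variables go through ``scipy.optimize.milp``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.optimize import LinearConstraint, linprog, milp

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"
FAILED = "failed"


@dataclass
class Solution:
    status: str
    objective: Optional[float]
    values: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == OPTIMAL

    def __getitem__(self, name: str) -> float:
        return self.values[name]


class Program:
    """Accumulates variables and linear constraints; solves min or max."""

    def __init__(self) -> None:
        self._names: list[str] = []
        self._index: dict[str, int] = {}
        self._lb: list[float] = []
        self._ub: list[float] = []
        self._integer: list[bool] = []
        # constraints as (coeff dict by index, lo, hi)
        self._rows: list[tuple[dict[int, float], float, float]] = []
        self._obj: dict[int, float] = {}

    # ---- variables -----------------------------------------------------
    def add_var(
        self,
        name: str,
        lb: float = 0.0,
        ub: float = np.inf,
        integer: bool = False,
        obj: float = 0.0,
    ) -> int:
        if name in self._index:
            raise ValueError(f"duplicate variable {name!r}")
        idx = len(self._names)
        self._names.append(name)
        self._index[name] = idx
        self._lb.append(lb)
        self._ub.append(ub)
        self._integer.append(integer)
        if obj:
            self._obj[idx] = obj
        return idx

    def add_binary(self, name: str, obj: float = 0.0) -> int:
        return self.add_var(name, 0.0, 1.0, integer=True, obj=obj)

    def has_var(self, name: str) -> bool:
        return name in self._index

    def set_bounds(self, name: str, lb: float, ub: float) -> None:
        idx = self._index[name]
        self._lb[idx] = lb
        self._ub[idx] = ub

    def get_bounds(self, name: str) -> tuple[float, float]:
        idx = self._index[name]
        return self._lb[idx], self._ub[idx]

    # ---- constraints / objective --------------------------------------
    def _resolve(self, coeffs: dict[str, float]) -> dict[int, float]:
        out: dict[int, float] = {}
        for name, c in coeffs.items():
            if c == 0.0:
                continue
            idx = self._index[name]
            out[idx] = out.get(idx, 0.0) + c
        return out

    def add_constr(
        self, coeffs: dict[str, float], lo: float = -np.inf, hi: float = np.inf
    ) -> int:
        self._rows.append((self._resolve(coeffs), lo, hi))
        return len(self._rows) - 1

    def add_eq(self, coeffs: dict[str, float], rhs: float = 0.0) -> int:
        return self.add_constr(coeffs, rhs, rhs)

    def add_le(self, coeffs: dict[str, float], rhs: float) -> int:
        return self.add_constr(coeffs, -np.inf, rhs)

    def add_ge(self, coeffs: dict[str, float], rhs: float) -> int:
        return self.add_constr(coeffs, rhs, np.inf)

    def set_objective(self, coeffs: dict[str, float]) -> None:
        self._obj = self._resolve(coeffs)

    # ---- solve ---------------------------------------------------------
    def _matrix(self) -> tuple[sparse.csr_matrix, np.ndarray, np.ndarray]:
        n = len(self._names)
        rows, cols, vals = [], [], []
        lo = np.empty(len(self._rows))
        hi = np.empty(len(self._rows))
        for i, (coeffs, a, b) in enumerate(self._rows):
            lo[i], hi[i] = a, b
            for j, c in coeffs.items():
                rows.append(i)
                cols.append(j)
                vals.append(c)
        A = sparse.csr_matrix((vals, (rows, cols)), shape=(len(self._rows), n))
        return A, lo, hi

    def solve(self, sense: str = "max") -> Solution:
        if sense not in ("max", "min"):
            raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
        n = len(self._names)
        c = np.zeros(n)
        for j, v in self._obj.items():
            c[j] = v
        sign = -1.0 if sense == "max" else 1.0
        lb = np.array(self._lb)
        ub = np.array(self._ub)
        if any(self._integer):
            sol = self._solve_milp(sign * c, lb, ub)
        else:
            sol = self._solve_lp(sign * c, lb, ub)
        if sol.ok and sol.objective is not None:
            sol.objective *= sign
        return sol

    def _solve_lp(self, c: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> Solution:
        A, lo, hi = self._matrix()
        eq = lo == hi
        A_eq = A[eq] if eq.any() else None
        b_eq = lo[eq] if eq.any() else None
        ineq = ~eq
        A_ub_parts, b_ub_parts = [], []
        if ineq.any():
            Ai, loi, hii = A[ineq], lo[ineq], hi[ineq]
            fin_hi = np.isfinite(hii)
            fin_lo = np.isfinite(loi)
            if fin_hi.any():
                A_ub_parts.append(Ai[fin_hi])
                b_ub_parts.append(hii[fin_hi])
            if fin_lo.any():
                A_ub_parts.append(-Ai[fin_lo])
                b_ub_parts.append(-loi[fin_lo])
        A_ub = sparse.vstack(A_ub_parts).tocsr() if A_ub_parts else None
        b_ub = np.concatenate(b_ub_parts) if b_ub_parts else None
        res = linprog(
            c,
            A_ub=A_ub,
            b_ub=b_ub,
            A_eq=A_eq,
            b_eq=b_eq,
            bounds=np.column_stack([lb, ub]),
            method="highs",
        )
        status = {0: OPTIMAL, 2: INFEASIBLE, 3: UNBOUNDED}.get(res.status, FAILED)
        values = (
            {name: float(res.x[j]) for name, j in self._index.items()}
            if res.x is not None
            else {}
        )
        return Solution(status=status, objective=float(res.fun) if res.success else None,
                        values=values)

    def _solve_milp(self, c: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> Solution:
        import warnings

        from scipy.optimize import Bounds

        A, lo, hi = self._matrix()
        constraints = LinearConstraint(A, lo, hi) if A.shape[0] else ()
        with warnings.catch_warnings():
            # the HiGHS pass-through options below trigger a benign
            # "unrecognized options" RuntimeWarning from scipy
            warnings.simplefilter("ignore", RuntimeWarning)
            res = milp(
                c,
                constraints=constraints,
                bounds=Bounds(lb, ub),
                integrality=np.array(self._integer, dtype=int),
                options={
                    "mip_rel_gap": 0.0,
                    "presolve": True,
                    # a big-M of 1000 times the HiGHS default integrality
                    # tolerance (1e-6) would leak exactly epsilon-sized
                    # flux through a "zero" binary; tighten it
                    "mip_feasibility_tolerance": 1e-9,
                    "primal_feasibility_tolerance": 1e-9,
                },
            )
        status = {0: OPTIMAL, 2: INFEASIBLE, 3: UNBOUNDED}.get(res.status, FAILED)
        values = (
            {name: float(res.x[j]) for name, j in self._index.items()}
            if res.x is not None
            else {}
        )
        return Solution(status=status, objective=float(res.fun) if res.success else None,
                        values=values)
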