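"""Thin linear-programming layer with interchangeable backends.

Problems are posed as  maximize c.x  subject to  A_eq.x = b_eq,
A_ub.x <= b_ub, lb <= x <= ub.  Two backends are provided: scipy's HiGHS
(default) and GLPK via swiglpk.  Both return the same (status, x, objective)
triple with status in {"optimal", "infeasible", "unbounded"}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LinearProgram", "solve", "BACKENDS", "SolverError"]

BACKENDS = ("highs", "glpk")


class SolverError(Exception):
    """Raised when a backend fails for reasons other than LP status."""


@dataclass
class LinearProgram:
    c: np.ndarray
    A_eq: np.ndarray | None = None
    b_eq: np.ndarray | None = None
    A_ub: np.ndarray | None = None
    b_ub: np.ndarray | None = None
    lb: np.ndarray = field(default=None)  # type: ignore[assignment]
    ub: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.c)
        if self.lb is None:
            self.lb = np.full(n, -np.inf)
        if self.ub is None:
            self.ub = np.full(n, np.inf)


def solve(lp: LinearProgram, backend: str = "highs", tol: float = 1e-9):
    """Solve ``lp``; return ``(status, x, objective)``.

    ``x`` and ``objective`` are None unless status is ``optimal``.
    """
    if backend == "highs":
        return _solve_highs(lp, tol)
    if backend == "glpk":
        return _solve_glpk(lp, tol)
    raise ValueError(f"unknown LP backend {backend!r}; choose from {BACKENDS}")


def _solve_highs(lp: LinearProgram, tol: float):
    from scipy.optimize import linprog

    res = linprog(
        -lp.c,
        A_ub=lp.A_ub,
        b_ub=lp.b_ub,
        A_eq=lp.A_eq,
        b_eq=lp.b_eq,
        bounds=np.column_stack([lp.lb, lp.ub]),
        method="highs",
        options={"primal_feasibility_tolerance": tol, "dual_feasibility_tolerance": tol},
    )
    if res.status == 0:
        return "optimal", np.asarray(res.x), float(lp.c @ res.x)
    if res.status == 2:
        return "infeasible", None, None
    if res.status == 3:
        return "unbounded", None, None
    raise SolverError(f"HiGHS failed: status {res.status}: {res.message}")


def _solve_glpk(lp: LinearProgram, tol: float):
    import swiglpk as glp

    n = len(lp.c)
    rows = []
    if lp.A_eq is not None and len(lp.A_eq):
        for i in range(lp.A_eq.shape[0]):
            rows.append((lp.A_eq[i], "eq", float(lp.b_eq[i])))
    if lp.A_ub is not None and len(lp.A_ub):
        for i in range(lp.A_ub.shape[0]):
            rows.append((lp.A_ub[i], "ub", float(lp.b_ub[i])))
    prob = glp.glp_create_prob()
    try:
        glp.glp_set_obj_dir(prob, glp.GLP_MAX)
        glp.glp_add_cols(prob, n)
        for j in range(n):
            lbj, ubj = float(lp.lb[j]), float(lp.ub[j])
            if np.isfinite(lbj) and np.isfinite(ubj):
                kind = glp.GLP_FX if lbj == ubj else glp.GLP_DB
                glp.glp_set_col_bnds(prob, j + 1, kind, lbj, ubj)
            elif np.isfinite(lbj):
                glp.glp_set_col_bnds(prob, j + 1, glp.GLP_LO, lbj, 0.0)
            elif np.isfinite(ubj):
                glp.glp_set_col_bnds(prob, j + 1, glp.GLP_UP, 0.0, ubj)
            else:
                glp.glp_set_col_bnds(prob, j + 1, glp.GLP_FR, 0.0, 0.0)
            glp.glp_set_obj_coef(prob, j + 1, float(lp.c[j]))
        if rows:
            glp.glp_add_rows(prob, len(rows))
            for i, (coefs, kind, rhs) in enumerate(rows):
                if kind == "eq":
                    glp.glp_set_row_bnds(prob, i + 1, glp.GLP_FX, rhs, rhs)
                else:
                    glp.glp_set_row_bnds(prob, i + 1, glp.GLP_UP, 0.0, rhs)
                nz = np.nonzero(coefs)[0]
                ind = glp.intArray(len(nz) + 1)
                val = glp.doubleArray(len(nz) + 1)
                for k, j in enumerate(nz, start=1):
                    ind[k] = int(j) + 1
                    val[k] = float(coefs[j])
                glp.glp_set_mat_row(prob, i + 1, len(nz), ind, val)
        parm = glp.glp_smcp()
        glp.glp_init_smcp(parm)
        parm.msg_lev = glp.GLP_MSG_OFF
        parm.presolve = glp.GLP_ON
        ret = glp.glp_simplex(prob, parm)
        status = glp.glp_get_status(prob)
        if status == glp.GLP_OPT:
            x = np.array([glp.glp_get_col_prim(prob, j + 1) for j in range(n)])
            return "optimal", x, float(lp.c @ x)
        if status in (glp.GLP_INFEAS, glp.GLP_NOFEAS):
            return "infeasible", None, None
        if status == glp.GLP_UNBND:
            return "unbounded", None, None
        # presolver can return nonzero codes for infeasible/unbounded problems
        if ret == glp.GLP_ENOPFS:
            return "infeasible", None, None
        if ret == glp.GLP_ENODFS:
            return "unbounded", None, None
        raise SolverError(f"GLPK failed: simplex return {ret}, status {status}")
    finally:
        glp.glp_delete_prob(prob)
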