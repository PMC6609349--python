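"""Thin deterministic wrapper around the GLPK simplex solver (swiglpk).

The producibility estimator solves thousands of structurally identical LPs
that differ only in bounds and objective, so the problem is built once and
mutated in place; the simplex warm-starts from the previous basis.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple

import swiglpk as glp

_INF = math.inf

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"


class SolverError(RuntimeError):
    """Numerical failure that persisted after a tightened-tolerance retry."""


class LinearProgram:
    """maximize c·v  s.t.  S v = 0,  lb ≤ v ≤ ub  (rows fixed at zero)."""

    def __init__(self, n_rows: int, n_cols: int):
        self._lp = glp.glp_create_prob()
        glp.glp_set_obj_dir(self._lp, glp.GLP_MAX)
        if n_rows:
            glp.glp_add_rows(self._lp, n_rows)
        if n_cols:
            glp.glp_add_cols(self._lp, n_cols)
        for i in range(1, n_rows + 1):
            glp.glp_set_row_bnds(self._lp, i, glp.GLP_FX, 0.0, 0.0)
        self.n_rows = n_rows
        self.n_cols = n_cols
        self._parm = glp.glp_smcp()
        glp.glp_init_smcp(self._parm)
        self._parm.msg_lev = glp.GLP_MSG_OFF
        # primal/dual feasibility tolerances well below the 1e-3
        # producibility threshold
        self._parm.tol_bnd = 1e-9
        self._parm.tol_dj = 1e-9
        self._obj_cols: List[int] = []

    def __del__(self):  # pragma: no cover
        try:
            glp.glp_delete_prob(self._lp)
        except Exception:
            pass

    def set_matrix(self, entries: Sequence[Tuple[int, int, float]]) -> None:
        """Load the sparse constraint matrix from 0-based (row, col, value)."""
        n = len(entries)
        ia = glp.intArray(n + 1)
        ja = glp.intArray(n + 1)
        ar = glp.doubleArray(n + 1)
        for k, (i, j, v) in enumerate(entries, start=1):
            ia[k] = i + 1
            ja[k] = j + 1
            ar[k] = float(v)
        glp.glp_load_matrix(self._lp, n, ia, ja, ar)

    def set_col_bounds(self, col: int, lb: float, ub: float) -> None:
        j = col + 1
        if lb == ub:
            glp.glp_set_col_bnds(self._lp, j, glp.GLP_FX, lb, ub)
        elif lb == -_INF and ub == _INF:
            glp.glp_set_col_bnds(self._lp, j, glp.GLP_FR, 0.0, 0.0)
        elif ub == _INF:
            glp.glp_set_col_bnds(self._lp, j, glp.GLP_LO, lb, 0.0)
        elif lb == -_INF:
            glp.glp_set_col_bnds(self._lp, j, glp.GLP_UP, 0.0, ub)
        else:
            glp.glp_set_col_bnds(self._lp, j, glp.GLP_DB, lb, ub)

    def set_objective(self, cols: Dict[int, float]) -> None:
        """Replace the objective with the given 0-based col → coefficient map."""
        for j in self._obj_cols:
            glp.glp_set_obj_coef(self._lp, j + 1, 0.0)
        for j, c in cols.items():
            glp.glp_set_obj_coef(self._lp, j + 1, float(c))
        self._obj_cols = list(cols)

    def solve(self) -> Tuple[str, float]:
        """Run the (warm-started) simplex; return (status, objective value)."""
        ret = glp.glp_simplex(self._lp, self._parm)
        status = glp.glp_get_status(self._lp)
        if ret != 0 or status in (glp.GLP_UNDEF,):
            # numerical trouble: rebuild the basis and retry with tighter
            # tolerances before giving up
            glp.glp_std_basis(self._lp)
            tight = glp.glp_smcp()
            glp.glp_init_smcp(tight)
            tight.msg_lev = glp.GLP_MSG_OFF
            tight.tol_bnd = 1e-11
            tight.tol_dj = 1e-11
            ret = glp.glp_simplex(self._lp, tight)
            status = glp.glp_get_status(self._lp)
            if ret != 0 or status == glp.GLP_UNDEF:
                raise SolverError(f"GLPK simplex failed (ret={ret}, status={status})")
        if status == glp.GLP_OPT:
            return OPTIMAL, glp.glp_get_obj_val(self._lp)
        if status in (glp.GLP_NOFEAS, glp.GLP_INFEAS):
            return INFEASIBLE, math.nan
        if status == glp.GLP_UNBND:
            return UNBOUNDED, _INF
        raise SolverError(f"unexpected GLPK status {status}")  # pragma: no cover
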