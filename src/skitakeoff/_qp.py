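"""Exact active-set solver for box-bounded diagonal quadratic programs.

Solves ``min_x  x' diag(d) x  s.t.  A x = b,  lb <= x <= ub`` with d > 0.
The Hessian is diagonal and strictly positive, so each working set has a
closed-form KKT solution; variables are clamped to (released from) bounds one
at a time until primal and dual feasibility hold.  Problems here are tiny
(tens of variables), so the exact solve is both faster and far more accurate
than a general NLP solver.
"""

from __future__ import annotations

import numpy as np

__all__ = ["solve_diag_qp", "QPError"]


class QPError(RuntimeError):
    pass


def _kkt_solve(d, A, b, lo_set, hi_set, lb, ub):
    """Closed-form solution with the given working set of active bounds."""
    nx = len(d)
    free = ~(lo_set | hi_set)
    x = np.where(lo_set, lb, 0.0) + np.where(hi_set, ub, 0.0)
    r = b - A[:, ~free] @ x[~free] if (~free).any() else b.copy()
    Af = A[:, free]
    Dinv = 1.0 / (2.0 * d[free])
    G = (Af * Dinv) @ Af.T
    try:
        lam = np.linalg.solve(G, -r)
    except np.linalg.LinAlgError:
        lam = np.linalg.lstsq(G, -r, rcond=None)[0]
    x[free] = -Dinv * (Af.T @ lam)
    return x, lam, free


def solve_diag_qp(
    d: np.ndarray,
    A: np.ndarray,
    b: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    max_iter: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Returns (x, lambda) at the unique optimum.

    ``lambda`` are the equality-constraint multipliers, so the stationarity
    residual ``2 d x + A' lambda`` vanishes on free variables and gives the
    bound multipliers on active ones.
    """
    d = np.asarray(d, dtype=float)
    A = np.atleast_2d(np.asarray(A, dtype=float))
    b = np.asarray(b, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    nx = len(d)
    if np.any(d <= 0):
        raise QPError("diagonal Hessian must be strictly positive")
    lo_set = np.zeros(nx, dtype=bool)
    hi_set = np.zeros(nx, dtype=bool)
    max_iter = max_iter or 20 * (nx + 1) * (nx + 1)
    tol = 1e-10

    for _ in range(max_iter):
        x, lam, free = _kkt_solve(d, A, b, lo_set, hi_set, lb, ub)
        # primal feasibility: clamp the worst bound violation among free vars
        viol_lo = np.where(free, lb - x, -np.inf)
        viol_hi = np.where(free, x - ub, -np.inf)
        worst = max(viol_lo.max(initial=-np.inf), viol_hi.max(initial=-np.inf))
        if worst > tol:
            if viol_lo.max() >= viol_hi.max():
                lo_set[int(np.argmax(viol_lo))] = True
            else:
                hi_set[int(np.argmax(viol_hi))] = True
            continue
        # dual feasibility: release the most negative bound multiplier
        mu = 2.0 * d * x + A.T @ lam
        bad_lo = np.where(lo_set, -mu, -np.inf)  # need mu >= 0 at lower bound
        bad_hi = np.where(hi_set, mu, -np.inf)  # need mu <= 0 at upper bound
        worst_dual = max(bad_lo.max(initial=-np.inf), bad_hi.max(initial=-np.inf))
        if worst_dual > tol:
            if bad_lo.max() >= bad_hi.max():
                lo_set[int(np.argmax(bad_lo))] = False
            else:
                hi_set[int(np.argmax(bad_hi))] = False
            continue
        return x, lam
    raise QPError("active-set iteration did not settle")  # pragma: no cover
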