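"""Dense convex quadratic programming with equality and box constraints.

Solves   minimize  1/2 z' H z + g' z
         s.t.      C z = d,   lb <= z <= ub

for positive-definite H (the caller adds a tiny ridge).  Problems here are
small (tens of variables), so a direct strategy works well:

1. solve the equality-only KKT system; if the solution respects the box,
   it is optimal;
2. otherwise run an active-set iteration on the box constraints (fix
   variables at violated bounds, re-solve, release fixed variables whose
   multiplier has the wrong sign);
3. if the active set does not settle, fall back to
   ``scipy.optimize.minimize(method='trust-constr')`` and polish the result
   by re-solving the KKT system on the free variables.

The path taken is reported in :class:`QPResult.status`; every route is
deterministic given the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["QPResult", "solve_qp"]


@dataclass
class QPResult:
    z: np.ndarray
    status: str          # 'optimal', 'optimal_active_set', 'optimal_polished'
    objective: float
    n_active: int


def _kkt_solve(H, g, C, d, fixed_idx, fixed_val):
    """Solve the equality-KKT system with some coordinates pinned."""
    n = H.shape[0]
    rows = [C] if C.size else []
    rhs = [d] if C.size else []
    if len(fixed_idx):
        E = np.zeros((len(fixed_idx), n))
        E[np.arange(len(fixed_idx)), fixed_idx] = 1.0
        rows.append(E)
        rhs.append(fixed_val)
    if rows:
        A = np.vstack(rows)
        b = np.concatenate(rhs)
        m = A.shape[0]
        K = np.block([[H, A.T], [A, np.zeros((m, m))]])
        r = np.concatenate([-g, b])
        sol, *_ = np.linalg.lstsq(K, r, rcond=None)
        return sol[:n], sol[n:]
    sol, *_ = np.linalg.lstsq(H, -g, rcond=None)
    return sol, np.empty(0)


def _box_violation(z, lb, ub):
    return float(np.max(np.maximum(lb - z, z - ub), initial=0.0))


def solve_qp(H: np.ndarray, g: np.ndarray, C: np.ndarray, d: np.ndarray,
             lb: np.ndarray, ub: np.ndarray, tol: float = 1e-9,
             max_iter: int | None = None) -> QPResult:
    H = np.asarray(H, dtype=float)
    g = np.asarray(g, dtype=float)
    C = np.atleast_2d(np.asarray(C, dtype=float)) if np.size(C) else np.empty((0, H.shape[0]))
    d = np.asarray(d, dtype=float).ravel() if np.size(d) else np.empty(0)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    n = H.shape[0]
    if np.any(lb > ub):
        raise ValueError("infeasible box constraints (lb > ub)")
    scale = max(1.0, float(np.max(np.abs(ub[np.isfinite(ub)]), initial=1.0)))
    box_tol = tol * scale

    def finish(z, status, n_active):
        obj = float(0.5 * z @ H @ z + g @ z)
        return QPResult(np.clip(z, lb, ub), status, obj, n_active)

    # 1. equality-only solve
    z, _ = _kkt_solve(H, g, C, d, np.empty(0, dtype=int), np.empty(0))
    if _box_violation(z, lb, ub) <= box_tol:
        return finish(z, "optimal", 0)

    # 2. active-set iteration on the box
    max_iter = max_iter or 4 * n + 10
    fixed: dict[int, float] = {}
    for i in np.flatnonzero(z < lb - box_tol):
        fixed[int(i)] = lb[i]
    for i in np.flatnonzero(z > ub + box_tol):
        fixed[int(i)] = ub[i]
    for _ in range(max_iter):
        idx = np.array(sorted(fixed), dtype=int)
        val = np.array([fixed[i] for i in idx])
        z, _ = _kkt_solve(H, g, C, d, idx, val)
        viol_lo = np.flatnonzero((z < lb - box_tol) & ~np.isin(np.arange(n), idx))
        viol_hi = np.flatnonzero((z > ub + box_tol) & ~np.isin(np.arange(n), idx))
        if viol_lo.size or viol_hi.size:
            # add the single most violated bound (Bland-like, avoids cycling)
            cand = [(lb[i] - z[i], int(i), lb[i]) for i in viol_lo]
            cand += [(z[i] - ub[i], int(i), ub[i]) for i in viol_hi]
            _, i, v = max(cand)
            fixed[i] = v
            continue
        # multiplier check: gradient of the Lagrangian on fixed coordinates
        grad = H @ z + g
        if C.size:
            # project out the equality multipliers: residual gradient on the
            # fixed coordinates after removing the span of C rows
            lam, *_ = np.linalg.lstsq(C.T, grad, rcond=None)
            grad = grad - C.T @ lam
        release = None
        worst = -box_tol * max(1.0, float(np.abs(grad).max()))
        for i in idx:
            # at a lower bound the reduced gradient must be >= 0, at an upper
            # bound <= 0; otherwise releasing the bound improves the objective
            mu = grad[i] if fixed[i] == lb[i] else -grad[i]
            if mu < worst:
                worst = mu
                release = int(i)
        if release is None:
            return finish(z, "optimal_active_set", len(fixed))
        del fixed[release]

    # 3. fall back to trust-constr, then polish
    z0 = np.clip(z, lb, ub)
    constraints = []
    if C.size:
        constraints.append(optimize.LinearConstraint(C, d, d))
    res = optimize.minimize(
        lambda x: 0.5 * x @ H @ x + g @ x, z0, jac=lambda x: H @ x + g,
        hess=lambda x: H, method="trust-constr", constraints=constraints,
        bounds=optimize.Bounds(lb, ub),
        options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 2000, "verbose": 0})
    z = res.x
    at_lo = np.abs(z - lb) <= 1e-6 * scale
    at_hi = np.abs(z - ub) <= 1e-6 * scale
    idx = np.flatnonzero(at_lo | at_hi)
    val = np.where(at_lo, lb, ub)[idx]
    z_pol, _ = _kkt_solve(H, g, C, d, idx, val)
    if _box_violation(z_pol, lb, ub) <= box_tol:
        obj_pol = 0.5 * z_pol @ H @ z_pol + g @ z_pol
        if obj_pol <= res.fun + box_tol:
            return finish(z_pol, "optimal_polished", int(idx.size))
    return finish(z, "optimal_polished", int(idx.size))
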