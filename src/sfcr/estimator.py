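"""Flux estimation by constrained weighted least squares (one convex QP).

Fixed-pool problem:

    min  sum_i eps_MID(t_i)' W_MID eps_MID(t_i) + eps_V' W_V eps_V
    s.t. S(t_i) v dt_i + eps_MID(t_i) = Y(t_i)       for every interval i
         N v = 0                                      (metabolic steady state)
         v_exc + eps_V = v_exc,measured               (soft-fitted boundaries)
         v_min <= v <= v_max,  |eps| <= 1e6

Variable-pool variant: the diagonal pool matrix P becomes a nonnegative
decision variable with its own soft measurement constraint
P + eps_P = P_measured and weight W_pool; since the measured fractions x are
data, the constraints stay jointly linear in (v, P) and the problem remains a
convex QP.

Because the residual bounds (+/- 1e6) dwarf any realistic residual, the
epsilons are eliminated by substitution and the program is solved over (v)
or (v, P) only.  A 1e-12 ridge on the decision variables tie-breaks flat
directions toward the minimum-norm optimizer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .assembly import AssembledSystem
from .model_io import MetabolicNetwork
from .qp import solve_qp

__all__ = ["SolverOptions", "FluxEstimate", "solve_sfcr",
           "solve_sfcr_variable_pools", "zero_small_fluxes", "turnover_time",
           "write_results", "FLUX_TOLERANCE"]

#: Fluxes below this magnitude (nmol gDW^-1 s^-1) are treated as zero.
FLUX_TOLERANCE = 1.0e-6


@dataclass
class SolverOptions:
    ridge: float = 1e-12          # tie-break regularization on decision vars
    tol: float = 1e-9             # bound/KKT tolerance
    exchange_scale: float = 1.0   # optional rescaling of measured boundary fluxes


@dataclass
class FluxEstimate:
    """Solution of the regression: fluxes, residuals and chi-square."""

    reaction_ids: list[str]
    v: np.ndarray
    eps_mid: list[np.ndarray]        # per interval, Y - S v dt (concentration units)
    eps_flux: np.ndarray             # v_exc,measured - v_exc
    chi2: float
    solver_status: str
    row_index: list[tuple[str, int]]
    boundary_reactions: list[str]
    weights: object                  # WeightModel used in the fit
    eps_pool: np.ndarray = field(default_factory=lambda: np.empty(0))
    P_est: dict[str, float] = field(default_factory=dict)
    mode: str = "fixed_pools"

    def flux(self, reaction_id: str) -> float:
        return float(self.v[self.reaction_ids.index(reaction_id)])

    @property
    def n_measurements(self) -> int:
        n = sum(e.size for e in self.eps_mid) + self.eps_flux.size
        if self.mode == "variable_pools":
            n += self.eps_pool.size
        return n

    def recompute_chi2(self) -> float:
        """Weighted sum of squared residuals, independent of the solver."""
        w = self.weights
        total = sum(float(e @ (w.w_mid * e)) for e in self.eps_mid)
        total += float(self.eps_flux @ (w.w_flux * self.eps_flux))
        if self.mode == "variable_pools" and self.eps_pool.size:
            total += float(self.eps_pool @ (w.w_pool * self.eps_pool))
        return total


def _boundary_arrays(system: AssembledSystem, boundary, network: MetabolicNetwork,
                     exchange_scale: float):
    """Measured boundary fluxes as (column indices, means, weights)."""
    reactions = system.weights.boundary_reactions
    cols = np.array([network.reaction_index(r) for r in reactions], dtype=int)
    means = np.empty(len(reactions))
    for i, r in enumerate(reactions):
        if isinstance(boundary, Mapping):
            means[i] = boundary[r][0] if np.iterable(boundary[r]) else boundary[r]
        else:  # DataFrame in the dataset schema
            row = boundary[boundary["reaction"] == r]
            means[i] = float(row["mean"].iloc[0])
    return cols, means * exchange_scale, system.weights.w_flux


def _solve(system: AssembledSystem, network: MetabolicNetwork, boundary,
           options: SolverOptions, pool_measurements=None):
    """Shared QP assembly for the fixed- and variable-pool variants."""
    opt = options or SolverOptions()
    A_mid, y_mid, w_rows = system.stacked()
    cols, exc_mean, w_flux = _boundary_arrays(system, boundary, network,
                                              opt.exchange_scale)
    r = network.n_reactions
    variable = pool_measurements is not None
    if variable:
        pool_mets = system.weights.pool_metabolites
        npool = len(pool_mets)
        met_col = {m: r + i for i, m in enumerate(pool_mets)}
        # residual rows: P dx - S v dt, target 0
        A_mid = np.hstack([-A_mid, np.zeros((A_mid.shape[0], npool))])
        dx = np.concatenate(system.dx_blocks)
        for i, (met, _) in enumerate(system.row_index * system.n_intervals):
            A_mid[i, met_col[met]] = dx[i]
        y_mid = np.zeros_like(y_mid)
        # pool measurement rows
        A_pool = np.zeros((npool, r + npool))
        A_pool[:, r:] = np.eye(npool)
        p_meas = np.array([pool_measurements[m][0] if np.iterable(pool_measurements[m])
                           else pool_measurements[m] for m in pool_mets])
        nvar = r + npool
    else:
        nvar = r
    A_flux = np.zeros((len(cols), nvar))
    A_flux[np.arange(len(cols)), cols] = 1.0
    blocks_A = [A_mid, A_flux]
    blocks_y = [y_mid, exc_mean]
    blocks_w = [w_rows, w_flux]
    if variable:
        blocks_A.append(A_pool)
        blocks_y.append(p_meas)
        blocks_w.append(system.weights.w_pool)
    A = np.vstack(blocks_A)
    y = np.concatenate(blocks_y)
    w = np.concatenate(blocks_w)
    Aw = A * w[:, None]
    H = 2.0 * (A.T @ Aw)
    ridge = opt.ridge * max(1.0, float(np.trace(H)) / max(nvar, 1))
    H[np.diag_indices_from(H)] += 2.0 * ridge
    g = -2.0 * (Aw.T @ y)
    C = np.hstack([network.N, np.zeros((network.n_metabolites, nvar - r))])
    d = np.zeros(network.n_metabolites)
    lb = np.concatenate([network.v_min, np.zeros(nvar - r)])
    ub = np.concatenate([network.v_max, np.full(nvar - r, np.inf)])
    res = solve_qp(H, g, C, d, lb, ub, tol=opt.tol)
    z = res.z
    v = z[:r]
    k = len(system.row_index)
    if variable:
        P_est = {m: float(z[r + i]) for i, m in enumerate(pool_mets)}
        pvec = np.array([P_est[m] for m, _ in system.row_index])
        eps_mid = [pvec * dxb - S @ v * dt
                   for S, dxb, dt in zip(system.S_blocks, system.dx_blocks, system.dt)]
        eps_pool = p_meas - z[r:]
    else:
        P_est, eps_pool = {}, np.empty(0)
        eps_mid = [Yb - S @ v * dt
                   for S, Yb, dt in zip(system.S_blocks, system.Y_blocks, system.dt)]
    eps_flux = exc_mean - v[cols]
    est = FluxEstimate(
        reaction_ids=list(network.reaction_ids), v=v, eps_mid=eps_mid,
        eps_flux=eps_flux, chi2=0.0, solver_status=res.status,
        row_index=list(system.row_index),
        boundary_reactions=list(system.weights.boundary_reactions),
        weights=system.weights, eps_pool=eps_pool, P_est=P_est,
        mode="variable_pools" if variable else "fixed_pools")
    est.chi2 = est.recompute_chi2()
    # steady-state sanity: the solver must honor N v = 0
    resid = float(np.max(np.abs(network.N @ v)))
    if resid > 1e-6 * max(1.0, float(np.max(np.abs(v)))):
        raise RuntimeError(f"solver returned non-steady solution (|Nv| = {resid:.2e})")
    return est


def solve_sfcr(system: AssembledSystem, network: MetabolicNetwork, boundary,
               options: SolverOptions | None = None) -> FluxEstimate:
    """Estimate steady-state fluxes with pools fixed at their measured means."""
    return _solve(system, network, boundary, options)


def solve_sfcr_variable_pools(system: AssembledSystem, network: MetabolicNetwork,
                              boundary, pool_measurements: Mapping,
                              options: SolverOptions | None = None) -> FluxEstimate:
    """Variant treating pool sizes as nonnegative decision variables.

    ``pool_measurements`` maps each tracked metabolite to (mean, sd); the
    means enter as soft targets weighted by the pool weights already present
    in the system's weight model (built in 'variable_pools' mode).
    """
    if system.weights.mode != "variable_pools":
        raise ValueError("system weights must be built with mode='variable_pools'")
    missing = [m for m, _ in system.row_index
               if m not in pool_measurements]
    if missing:
        raise KeyError(f"missing pool measurements for {sorted(set(missing))}")
    return _solve(system, network, boundary, options,
                  pool_measurements=pool_measurements)


def zero_small_fluxes(v: np.ndarray, tol: float = FLUX_TOLERANCE) -> np.ndarray:
    """Set fluxes with magnitude below ``tol`` to exactly zero."""
    out = np.array(v, dtype=float, copy=True)
    out[np.abs(out) < tol] = 0.0
    return out


def turnover_time(pool_mean: float, flux: float) -> float:
    """Pool turnover time (s) = pool size / flux; NaN when flux <= 0."""
    if flux <= 0:
        return float("nan")
    return pool_mean / flux


def write_results(estimate: FluxEstimate, out_dir: str | Path,
                  df: int | None = None, interval=None,
                  accepted: bool | None = None,
                  flux_tol: float = FLUX_TOLERANCE) -> None:
    """Write fluxes.csv and fit.json to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholded = zero_small_fluxes(estimate.v, flux_tol)
    pd.DataFrame({"reaction": estimate.reaction_ids, "v": estimate.v,
                  "v_thresholded": thresholded}).to_csv(out / "fluxes.csv", index=False)
    doc = {"chi2": estimate.chi2, "status": estimate.solver_status,
           "mode": estimate.mode, "n_measurements": estimate.n_measurements}
    if df is not None:
        doc["df"] = df
    if interval is not None:
        doc["interval"] = list(interval)
    if accepted is not None:
        doc["accepted"] = bool(accepted)
    if estimate.P_est:
        doc["P_est"] = estimate.P_est
    with open(out / "fit.json", "w") as fh:
        json.dump(doc, fh, indent=1)
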