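"""Non-parametric bootstrap confidence intervals by residual resampling.

The residuals of the base fit are resampled with replacement (MID residuals
pooled across isotopologues and intervals, boundary-flux residuals within
their own pool) and added to the *fitted* concentration changes to form a
bootstrap dataset; the QP is then re-solved and the refit parameters stored.
Confidence intervals are the 2.5th and 97.5th percentiles over (by default)
1000 replicates.

Residuals are defined in concentration-change (Y) units, so the perturbation
is applied in Y space — adding concentration residuals to dimensionless MID
fractions would be dimensionally inconsistent.  A stratified option resamples
each isotopologue row only from its own residuals across intervals, for use
when the residual scales differ strongly between rows.

When compartmentation is active, each replicate redraws c uniformly within
+/- 2.5 % (relative) of the best-fit parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .assembly import AssembledSystem, assemble
from .compartmentation import CompartmentationConfig, jitter_c
from .estimator import FluxEstimate, SolverOptions, solve_sfcr, solve_sfcr_variable_pools
from .gof import acceptance_interval, degrees_of_freedom
from .model_io import LabelingDataset, MetabolicNetwork, MIDBalanceSpec

__all__ = ["BootstrapConfig", "BootstrapResult", "bootstrap_fit"]


@dataclass
class BootstrapConfig:
    n_reps: int = 1000
    seed: int = 0
    alpha: float = 0.05
    stratify: bool = False
    max_failure_fraction: float = 0.10
    options: SolverOptions | None = None
    # compartmentation jitter (optional): needs the spec/dataset to rebuild S
    best_c: dict[str, float] = field(default_factory=dict)
    c_config: CompartmentationConfig | None = None
    spec: MIDBalanceSpec | None = None
    dataset: LabelingDataset | None = None


@dataclass
class BootstrapResult:
    samples: pd.DataFrame            # one row per successful replicate
    ci: pd.DataFrame                 # parameter, lower, upper
    chi2_ci: tuple[float, float]
    acceptance_fraction: float
    df: int
    seed: int
    n_failed: int


def _resample_mid(eps: np.ndarray, k: int, n_int: int, stratify: bool,
                  rng: np.random.Generator) -> np.ndarray:
    """Resample the pooled (or per-row stratified) MID residual vector."""
    if not stratify:
        return rng.choice(eps, size=eps.size, replace=True)
    mat = eps.reshape(n_int, k)
    out = np.empty_like(mat)
    for j in range(k):
        out[:, j] = rng.choice(mat[:, j], size=n_int, replace=True)
    return out.ravel()


def bootstrap_fit(base: FluxEstimate, system: AssembledSystem,
                  network: MetabolicNetwork, boundary,
                  config: BootstrapConfig | None = None) -> BootstrapResult:
    """Residual-resampling bootstrap around a solved base estimate."""
    cfg = config or BootstrapConfig()
    rng = np.random.default_rng(cfg.seed)
    k = len(system.row_index)
    n_int = system.n_intervals
    variable = base.mode == "variable_pools"
    jitter = bool(cfg.best_c) and cfg.c_config is not None
    if jitter and (cfg.spec is None or cfg.dataset is None):
        raise ValueError("c jitter requires spec and dataset in the config")

    # fitted values of the base model, in Y space
    yhat_blocks = [S @ base.v * dt for S, dt in zip(system.S_blocks, system.dt)]
    eps_mid = np.concatenate(base.eps_mid)
    exc_cols = [network.reaction_index(r) for r in base.boundary_reactions]
    vexc_hat = base.v[exc_cols]
    if variable:
        pvec = np.array([base.P_est[m] for m, _ in system.row_index])
        p_hat = np.array([base.P_est[m] for m in system.weights.pool_metabolites])

    param_names = list(network.reaction_ids)
    if variable:
        param_names += [f"P:{m}" for m in system.weights.pool_metabolites]
    if jitter:
        param_names += [f"c:{cid}" for cid in sorted(cfg.best_c)]

    rows, chi2s, n_failed = [], [], 0
    for _ in range(cfg.n_reps):
        eps_star = _resample_mid(eps_mid, k, n_int, cfg.stratify, rng)
        eps_v_star = rng.choice(base.eps_flux, size=base.eps_flux.size, replace=True)
        boundary_star = {r: (vexc_hat[i] + eps_v_star[i], None)
                         for i, r in enumerate(base.boundary_reactions)}
        sys_star = system
        if jitter:
            c_star = jitter_c(cfg.best_c, cfg.c_config.bootstrap_deviation, rng)
            sys_star = assemble(cfg.spec, cfg.dataset, system.weights, network,
                                c_params=c_star)
            yhat_star = [S @ base.v * dt for S, dt in zip(sys_star.S_blocks, sys_star.dt)]
        else:
            c_star = {}
            yhat_star = yhat_blocks
        y_star = [yh + eps_star[i * k:(i + 1) * k]
                  for i, yh in enumerate(yhat_star)]
        try:
            if variable:
                eps_p_star = rng.choice(base.eps_pool, size=base.eps_pool.size,
                                        replace=True)
                p_meas_star = {m: (p_hat[i] + eps_p_star[i], None)
                               for i, m in enumerate(system.weights.pool_metabolites)}
                dx_star = [y / pvec for y in y_star]
                sys_star = replace(sys_star, dx_blocks=dx_star,
                                   Y_blocks=[pvec * d for d in dx_star])
                est = solve_sfcr_variable_pools(sys_star, network, boundary_star,
                                                p_meas_star, cfg.options)
            else:
                sys_star = replace(sys_star, Y_blocks=y_star)
                est = solve_sfcr(sys_star, network, boundary_star, cfg.options)
        except Exception:  # noqa: BLE001 - count and move on
            n_failed += 1
            continue
        row = list(est.v)
        if variable:
            row += [est.P_est[m] for m in system.weights.pool_metabolites]
        if jitter:
            row += [c_star[cid] for cid in sorted(c_star)]
        rows.append(row)
        chi2s.append(est.chi2)

    if n_failed > cfg.max_failure_fraction * cfg.n_reps:
        raise RuntimeError(
            f"{n_failed}/{cfg.n_reps} bootstrap refits failed "
            f"(> {cfg.max_failure_fraction:.0%})")
    samples = pd.DataFrame(rows, columns=param_names)
    samples["chi2"] = chi2s
    lo, hi = 100 * (cfg.alpha / 2), 100 * (1 - cfg.alpha / 2)
    ci = pd.DataFrame({
        "parameter": param_names,
        "lower": [float(np.percentile(samples[p], lo)) for p in param_names],
        "upper": [float(np.percentile(samples[p], hi)) for p in param_names],
    })
    chi2_arr = np.array(chi2s)
    chi2_ci = (float(np.percentile(chi2_arr, lo)), float(np.percentile(chi2_arr, hi)))
    df = degrees_of_freedom(base.n_measurements, network)
    a_lo, a_hi = acceptance_interval(df, cfg.alpha)
    acc = float(np.mean((chi2_arr >= a_lo) & (chi2_arr <= a_hi)))
    return BootstrapResult(samples=samples, ci=ci, chi2_ci=chi2_ci,
                           acceptance_fraction=acc, df=df, seed=cfg.seed,
                           n_failed=n_failed)
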