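"""Measurement-error model and inverse-variance weights.

The chi-square objective of the regression needs a variance for every fitted
quantity.  MID measurement error sigma is taken per isotopologue as the
maximum across-replicate SD observed over the time course (it is assumed
time-independent); an isotopologue whose SD is zero at every time point
inherits the sigma of the next-lighter isotopologue.  Because residuals are
formed on isotopologue *concentration changes* Y(t_i) = P x(t_i + dt) -
P x(t_i), the fraction-space sigma is scaled by the mean pool size and the
difference of two independent equal-variance measurements doubles the
variance: Var(Y) = 2 (mu_P sigma)^2.

In variable-pool mode the pool size itself is a random variable and
Var(P x) = sigma_P^2 sigma_x^2 + sigma_P^2 mu_x^2 + sigma_x^2 mu_P^2 (product
of independent variables), again doubled for the difference of two
measurements; mu_x is estimated as the time-mean measured fraction.

All weights are inverse variances, so the optimal objective value of the
regression is the chi-square statistic used in the goodness-of-fit test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .model_io import LabelingDataset, MIDBalanceSpec

__all__ = ["WeightModel", "SigmaError", "mid_sigma", "build_weights"]


class SigmaError(ValueError):
    """Raised when a measurement SD needed for weighting is unavailable."""


@dataclass
class WeightModel:
    """Inverse-variance weights for the regression objective.

    ``row_index`` orders the tracked (metabolite, isotopologue) rows; all
    per-row arrays follow it.  ``w_mid`` weights concentration-change
    residuals, ``w_flux`` boundary-flux residuals and ``w_pool`` (variable-pool
    mode only) pool residuals.
    """

    row_index: list[tuple[str, int]]
    sigma_mid: np.ndarray           # fraction units, per row
    w_mid: np.ndarray               # 1 / Var(Y), per row
    boundary_reactions: list[str]
    w_flux: np.ndarray              # 1 / SD^2, per measured boundary flux
    pool_metabolites: list[str] = field(default_factory=list)
    w_pool: np.ndarray = field(default_factory=lambda: np.empty(0))
    mode: str = "fixed_pools"

    def __post_init__(self) -> None:
        for arr, name in ((self.sigma_mid, "sigma_mid"), (self.w_mid, "w_mid"),
                          (self.w_flux, "w_flux"), (self.w_pool, "w_pool")):
            a = np.asarray(arr, dtype=float)
            if a.size and (not np.all(np.isfinite(a)) or np.any(a <= 0)):
                raise SigmaError(f"{name} must be strictly positive and finite")


def mid_sigma(dataset: LabelingDataset, spec: MIDBalanceSpec,
              sigma_floor: float | None = None,
              sigma_override: float | Mapping[tuple[str, int], float] | None = None,
              ) -> dict[tuple[str, int], float]:
    """Per-isotopologue measurement SD in MID-fraction units.

    For each tracked (metabolite, M+j): the maximum over time points of the
    across-replicate SD of the measured fraction.  If that maximum is zero
    (common for heavy isotopologues at early times), the SD of M+(j-1) is
    used, resolved recursively toward M+0.  ``sigma_override`` short-circuits
    the estimate (scalar, or per-(metabolite, j) mapping); ``sigma_floor``
    replaces zeros that cannot be resolved by the fallback.
    """
    out: dict[tuple[str, int], float] = {}
    if np.isscalar(sigma_override):
        for b in spec.balances:
            for j in range(b.n_carbons + 1):
                out[(b.metabolite_id, j)] = float(sigma_override)
        return out
    for b in spec.balances:
        met = b.metabolite_id
        sd = dataset.replicate_sd(met)          # (n_times, n+1)
        per_iso = sd.max(axis=0)
        # fallback: zero sigma inherits the next-lighter isotopologue's sigma
        for j in range(1, per_iso.size):
            if per_iso[j] == 0.0:
                per_iso[j] = per_iso[j - 1]
        for j in range(b.n_carbons + 1):
            s = float(per_iso[j])
            if sigma_override is not None and (met, j) in sigma_override:
                s = float(sigma_override[(met, j)])
            if s == 0.0 and sigma_floor is not None:
                s = float(sigma_floor)
            if s <= 0.0:
                raise SigmaError(
                    f"all isotopologues of {met!r} have zero replicate SD "
                    "(single-replicate data?); supply sigma_floor or "
                    "sigma_override")
            out[(met, j)] = s
    return out


def build_weights(dataset: LabelingDataset, spec: MIDBalanceSpec,
                  mode: str = "fixed_pools",
                  sigma_floor: float | None = None,
                  sigma_override=None) -> WeightModel:
    """Assemble the full :class:`WeightModel` for a dataset/spec pair.

    mode='fixed_pools':   Var(Y)_row = 2 (mu_P sigma)^2
    mode='variable_pools': Var(Y)_row = 2 (sigma_P^2 sigma^2 + sigma_P^2 mu_x^2
                           + sigma^2 mu_P^2), plus pool weights 1/sigma_P^2.
    """
    if mode not in ("fixed_pools", "variable_pools"):
        raise ValueError(f"unknown weight mode {mode!r}")
    sigma = mid_sigma(dataset, spec, sigma_floor=sigma_floor,
                      sigma_override=sigma_override)
    rows = spec.rows()
    sig = np.array([sigma[r] for r in rows])
    var_y = np.empty(len(rows))
    for i, (met, j) in enumerate(rows):
        mu_p, sd_p = dataset.pool(met)
        if mode == "fixed_pools":
            var_y[i] = 2.0 * (mu_p * sig[i]) ** 2
        else:
            mu_x = float(dataset._mean_array(met)[:, j].mean())
            var_y[i] = 2.0 * (sd_p ** 2 * sig[i] ** 2
                              + sd_p ** 2 * mu_x ** 2
                              + sig[i] ** 2 * mu_p ** 2)
    boundary = list(dataset.boundary_fluxes["reaction"])
    w_flux = np.empty(len(boundary))
    for i, rxn in enumerate(boundary):
        _, sd = dataset.boundary(rxn)
        if sd <= 0:
            raise SigmaError(
                f"boundary flux {rxn!r} has zero SD; supply a positive SD floor "
                "in the measurement table")
        w_flux[i] = 1.0 / sd ** 2
    pool_mets: list[str] = []
    w_pool = np.empty(0)
    if mode == "variable_pools":
        pool_mets = spec.tracked_metabolites
        w_pool = np.empty(len(pool_mets))
        for i, met in enumerate(pool_mets):
            _, sd_p = dataset.pool(met)
            if sd_p <= 0:
                raise SigmaError(f"pool of {met!r} has zero SD; variable-pool "
                                 "mode needs positive pool SDs")
            w_pool[i] = 1.0 / sd_p ** 2
    return WeightModel(row_index=rows, sigma_mid=sig, w_mid=1.0 / var_y,
                       boundary_reactions=boundary, w_flux=w_flux,
                       pool_metabolites=pool_mets, w_pool=w_pool, mode=mode)
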