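"""Goodness of fit: chi-square acceptance test, residual diagnostics and the
metabolic-steady-state ANOVA screen.

A fit is statistically acceptable at significance level alpha when its
chi-square statistic falls inside [chi2_{alpha/2}(df), chi2_{1-alpha/2}(df)],
with df = number of fitted measurements minus the rank of the stoichiometric
matrix N.  Measurements count every tracked isotopologue at every interval,
each fitted boundary flux, and (in variable-pool mode) each fitted pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .error_model import WeightModel
from .estimator import FluxEstimate
from .model_io import MetabolicNetwork

__all__ = ["GofResult", "degrees_of_freedom", "acceptance_interval",
           "evaluate_fit", "standardized_residuals", "steady_state_anova"]


@dataclass
class GofResult:
    chi2: float
    df: int
    alpha: float
    interval: tuple[float, float]
    accepted: bool


def degrees_of_freedom(n_measurements: int, network: MetabolicNetwork) -> int:
    """df = n_measurements - rank(N); errors when non-positive."""
    df = int(n_measurements) - network.rank()
    if df <= 0:
        raise ValueError(
            f"non-positive degrees of freedom ({n_measurements} measurements, "
            f"rank(N) = {network.rank()})")
    return df


def acceptance_interval(df: int, alpha: float = 0.05) -> tuple[float, float]:
    """Two-sided chi-square acceptance range [chi2_{a/2}(df), chi2_{1-a/2}(df)]."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return (float(stats.chi2.ppf(alpha / 2, df)),
            float(stats.chi2.ppf(1 - alpha / 2, df)))


def evaluate_fit(estimate: FluxEstimate, network: MetabolicNetwork,
                 alpha: float = 0.05) -> GofResult:
    """Chi-square acceptance verdict for a solved estimate."""
    df = degrees_of_freedom(estimate.n_measurements, network)
    lo, hi = acceptance_interval(df, alpha)
    return GofResult(chi2=estimate.chi2, df=df, alpha=alpha, interval=(lo, hi),
                     accepted=lo <= estimate.chi2 <= hi)


def standardized_residuals(estimate: FluxEstimate,
                           weights: WeightModel | None = None) -> pd.DataFrame:
    """Residuals divided by their modeled SD, with a normality summary.

    Returns a tidy table (measurement, residual, std_residual) whose attrs
    carry mean, SD and a Shapiro-Wilk normality p-value of the standardized
    residuals; under a well-specified error model they are ~N(0, 1).
    """
    w = weights or estimate.weights
    recs = []
    for i, e in enumerate(estimate.eps_mid):
        for (met, j), r, wi in zip(estimate.row_index, e, w.w_mid):
            recs.append((f"{met}:M+{j}@interval{i}", r, r * np.sqrt(wi)))
    for rxn, r, wi in zip(estimate.boundary_reactions, estimate.eps_flux, w.w_flux):
        recs.append((f"flux:{rxn}", r, r * np.sqrt(wi)))
    if estimate.mode == "variable_pools":
        for met, r, wi in zip(w.pool_metabolites, estimate.eps_pool, w.w_pool):
            recs.append((f"pool:{met}", r, r * np.sqrt(wi)))
    df = pd.DataFrame(recs, columns=["measurement", "residual", "std_residual"])
    z = df["std_residual"].to_numpy()
    df.attrs["mean"] = float(z.mean())
    df.attrs["sd"] = float(z.std(ddof=1)) if z.size > 1 else 0.0
    if z.size >= 3 and np.ptp(z) > 0:
        df.attrs["normality_p"] = float(stats.shapiro(z).pvalue)
    else:
        df.attrs["normality_p"] = float("nan")
    return df


def steady_state_anova(pool_timeseries: pd.DataFrame,
                       alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA of pool size across time points, per metabolite.

    A metabolite is declared 'steady' when the ANOVA p-value is >= alpha,
    i.e. no evidence that its pool changes over the time course.  Verdicts
    are advisory (a warning to the analyst), never an automatic exclusion.
    """
    out = []
    for met, sub in pool_timeseries.groupby("metabolite"):
        groups = [g["pool_size"].to_numpy()
                  for _, g in sub.groupby("time_s")]
        if len(groups) < 2 or any(len(g) < 2 for g in groups):
            raise ValueError(
                f"steady-state ANOVA for {met!r} needs >= 2 time points with "
                ">= 2 replicates each")
        f, p = stats.f_oneway(*groups)
        out.append((met, float(f), float(p), bool(p >= alpha)))
    return pd.DataFrame(out, columns=["metabolite", "F", "p_value", "steady"])
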