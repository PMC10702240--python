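"""Compartmentation coefficients by random sampling.

Compartment-specific MIDs are rarely measurable.  For a metabolite present in
both plastid and cytosol the total-pool balance is the sum of both
compartments' terms, and the unmeasured cytosolic MID is approximated as
c * (measured MID) with a scalar coefficient c per compartmented species.
Since making c a free optimization variable would render the constraints
bilinear, c is sampled uniformly from [0.1, 0.9] (the labeling dynamics are
assumed plastid-dominated), the QP is re-solved per sample, and the best-fit
parameterization is reported — which may not be the global optimum over c.
During bootstrap, c is redrawn within +/- 2.5 % (relative) of the best fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assembly import assemble
from .error_model import WeightModel
from .estimator import FluxEstimate, SolverOptions, solve_sfcr
from .model_io import LabelingDataset, MetabolicNetwork, MIDBalanceSpec

__all__ = ["CompartmentationConfig", "sample_c", "jitter_c",
           "fit_with_compartmentation", "CompartmentationResult"]


@dataclass
class CompartmentationConfig:
    c_param_ids: list[str]
    interval: tuple[float, float] = (0.1, 0.9)
    n_samples: int = 50
    seed: int = 0
    bootstrap_deviation: float = 0.025   # relative, +/- around the best-fit c
    share_c: bool = False                # one common draw for all coefficients

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("compartmentation interval must lie within (0, 1)")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass
class CompartmentationResult:
    best: FluxEstimate
    best_c: dict[str, float]
    trace: pd.DataFrame          # sample index, c values, chi2
    n_failed: int = 0


def sample_c(config: CompartmentationConfig,
             rng: np.random.Generator | None = None) -> list[dict[str, float]]:
    """Draw ``n_samples`` independent uniform c assignments (seeded)."""
    rng = rng or np.random.default_rng(config.seed)
    lo, hi = config.interval
    out = []
    for _ in range(config.n_samples):
        if config.share_c:
            v = float(rng.uniform(lo, hi))
            out.append({cid: v for cid in config.c_param_ids})
        else:
            out.append({cid: float(rng.uniform(lo, hi))
                        for cid in config.c_param_ids})
    return out


def jitter_c(best_c: dict[str, float], deviation: float,
             rng: np.random.Generator) -> dict[str, float]:
    """Redraw c uniformly within +/- ``deviation`` (relative), clipped to (0, 1)."""
    out = {}
    for cid, c in best_c.items():
        lo = max(c * (1 - deviation), 1e-9)
        hi = min(c * (1 + deviation), 1 - 1e-9)
        out[cid] = float(rng.uniform(lo, hi))
    return out


def fit_with_compartmentation(spec: MIDBalanceSpec, dataset: LabelingDataset,
                              network: MetabolicNetwork, weights: WeightModel,
                              config: CompartmentationConfig,
                              boundary=None,
                              options: SolverOptions | None = None,
                              ) -> CompartmentationResult:
    """Sample c, refit the QP per sample, return the minimum-chi2 solution.

    Reduces to a single plain fit when the spec has no compartment-scaled
    sources.  Failed samples are skipped with a warning entry in the trace;
    an all-failed sweep is an error.
    """
    if boundary is None:
        boundary = dataset.boundary_fluxes
    c_ids = spec.c_param_ids()
    if not c_ids:
        system = assemble(spec, dataset, weights, network)
        est = solve_sfcr(system, network, boundary, options)
        trace = pd.DataFrame({"sample": [0], "chi2": [est.chi2]})
        return CompartmentationResult(best=est, best_c={}, trace=trace)
    if set(config.c_param_ids) != set(c_ids):
        raise ValueError(f"config c_param_ids {config.c_param_ids} do not match "
                         f"the spec's {c_ids}")
    draws = sample_c(config)
    records, best, best_c, n_failed = [], None, None, 0
    for idx, c in enumerate(draws):
        try:
            system = assemble(spec, dataset, weights, network, c_params=c)
            est = solve_sfcr(system, network, boundary, options)
        except Exception:  # noqa: BLE001 - a bad sample must not kill the sweep
            n_failed += 1
            records.append({"sample": idx, **c, "chi2": np.nan})
            continue
        records.append({"sample": idx, **c, "chi2": est.chi2})
        if best is None or est.chi2 < best.chi2:
            best, best_c = est, c
    if best is None:
        raise RuntimeError("all compartmentation samples failed to solve")
    return CompartmentationResult(best=best, best_c=best_c,
                                  trace=pd.DataFrame(records), n_failed=n_failed)
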