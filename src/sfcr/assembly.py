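"""Discretized labeling balances: build S(t_i) and stack the linear system.

The labeling ODE P dx/dt = S v is discretized with a Forward Euler step over
each measurement interval:

    P x(t_i + dt_i) - P x(t_i) = S(t_i) v dt_i

Every entry of S(t_i) is a signed combination of *measured* MIDs evaluated at
the left endpoint t_i — no labeling simulation is involved anywhere.  The
assembled system holds one (S, Y) block per interval, ordered by time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .error_model import WeightModel
from .model_io import LabelingDataset, MetabolicNetwork, MIDBalanceSpec, MIDVector, SourceExpr

__all__ = ["AssembledSystem", "convolve_mids", "eval_source", "build_S", "assemble"]


def convolve_mids(a: MIDVector, b: MIDVector) -> MIDVector:
    """MID of a condensation product of two precursors (Cauchy product).

    result[j] = sum_k a[k] b[j-k]; length n_a + n_b + 1.  For normalized
    inputs the result is normalized (sum(a x b) = sum(a) sum(b)).
    """
    return MIDVector(f"({a.metabolite_id}+{b.metabolite_id})",
                     np.convolve(a.fractions, b.fractions))


def eval_source(expr: SourceExpr, dataset: LabelingDataset, time_index: int,
                c_params: Mapping[str, float] | None = None) -> np.ndarray:
    """Evaluate a source expression against replicate-mean MIDs at one time point."""
    c_params = c_params or {}
    return expr.evaluate(lambda met: dataset.mean_mid(met, time_index), c_params)


def build_S(spec: MIDBalanceSpec, dataset: LabelingDataset, time_index: int,
            network: MetabolicNetwork,
            c_params: Mapping[str, float] | None = None) -> np.ndarray:
    """Matrix S(t_i): tracked isotopologue rows x reaction columns.

    Entry [row(met, j), reaction] is the sum over the metabolite's balance
    terms for that reaction of coefficient * source_MID[j]; reactions absent
    from a balance contribute zero.
    """
    k = spec.n_rows
    S = np.zeros((k, network.n_reactions))
    row = 0
    j0 = 1 if spec.drop_m0 else 0
    for bal in spec.balances:
        n_iso = bal.n_carbons + 1 - j0
        for term in bal.terms:
            col = network.reaction_index(term.reaction_id)
            vec = eval_source(term.source, dataset, time_index, c_params)
            S[row:row + n_iso, col] += term.coeff * vec[j0:]
        row += n_iso
    return S


@dataclass
class AssembledSystem:
    """Stacked per-interval linear systems S(t_i) v dt_i ~= Y(t_i).

    ``S_blocks[i]`` is evaluated strictly from measurements at t_i;
    ``Y_blocks[i] = diag(mu_P) (xbar(t_{i+1}) - xbar(t_i))`` uses replicate
    means in concentration units (nmol gDW^-1).
    """

    S_blocks: list[np.ndarray]
    Y_blocks: list[np.ndarray]
    dt: np.ndarray
    weights: WeightModel
    row_index: list[tuple[str, int]]
    reaction_ids: list[str]
    c_params: dict = field(default_factory=dict)
    # per-row measured fraction changes, needed by the variable-pool variant
    dx_blocks: list[np.ndarray] = field(default_factory=list)

    @property
    def n_intervals(self) -> int:
        return len(self.S_blocks)

    @property
    def n_mid_measurements(self) -> int:
        return sum(y.size for y in self.Y_blocks)

    def stacked(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(A, y, w) with A = vstack(S_i dt_i), y = concat(Y_i), per-row weights."""
        A = np.vstack([S * dt for S, dt in zip(self.S_blocks, self.dt)])
        y = np.concatenate(self.Y_blocks)
        w = np.tile(self.weights.w_mid, self.n_intervals)
        return A, y, w


def assemble(spec: MIDBalanceSpec, dataset: LabelingDataset,
             weights: WeightModel, network: MetabolicNetwork,
             c_params: Mapping[str, float] | None = None) -> AssembledSystem:
    """Build all per-interval (S, Y) blocks for the regression."""
    c_params = dict(c_params or {})
    needed = set(spec.c_param_ids()) - set(c_params)
    if needed:
        raise KeyError(f"unresolved compartmentation coefficients: {sorted(needed)}")
    times = dataset.time_points
    if len(times) < 2:
        raise ValueError("need at least two unmasked time points")
    rows = spec.rows()
    if weights.row_index != rows:
        raise ValueError("weight model row order does not match the balance spec")
    pool_mean = np.array([dataset.pool(met)[0] for met, _ in rows])
    S_blocks, Y_blocks, dx_blocks = [], [], []
    for i in range(len(times) - 1):
        S_blocks.append(build_S(spec, dataset, i, network, c_params))
        dx = np.array([dataset._mean_array(met)[i + 1, j]
                       - dataset._mean_array(met)[i, j] for met, j in rows])
        dx_blocks.append(dx)
        Y_blocks.append(pool_mean * dx)
    return AssembledSystem(S_blocks=S_blocks, Y_blocks=Y_blocks,
                           dt=dataset.intervals, weights=weights,
                           row_index=rows, reaction_ids=list(network.reaction_ids),
                           c_params=c_params, dx_blocks=dx_blocks)
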