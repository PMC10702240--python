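"""Ground-truth labeling data for testing and validation.

The generator inverts the estimation model: given a fixture network, a
balance spec, a feasible steady-state flux vector v* and pool sizes, it
produces MID time courses either by

* :func:`simulate_labeling` — integrating the labeling ODE
  P dx/dt = S(x) v* exactly with a stiff-capable integrator, or
* :func:`euler_propagate` — applying the Forward Euler recursion
  x(t+dt) = x(t) + P^-1 S(x(t)) v* dt, which yields data for which the
  regression's equality constraints hold *exactly* (so an identifiable
  fixture must be recovered to solver precision).

Gaussian replicate noise is added separately by :func:`add_noise`.

Two fixtures emulate the shape of 13CO2 labeling experiments in
photoautotrophs (5 time points at 0/5/10/20/40 s, pools in nmol gDW^-1,
fluxes in nmol gDW^-1 s^-1):

``toy5``
    a linear chain of four metabolites (A-D) and five reactions
    (v1, v2, v3, vin, vexc) with 1-2 carbons per metabolite.
``mini_cbc``
    a small cyclic carbon-fixation fixture: a carboxylation step consuming a
    fully labeled CO2 source (FixedVector [0, 1]), a condensation
    (convolution of two triose units), an isomerization modeled as a
    reversible net flux, and a branch to two measured boundary fluxes — a
    starch-like sink and a sucrose-like sink drawing on the cytosolic
    fraction of a compartmented hexose pool (coefficient ``c_G``).  It
    exercises every source-expression kind.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_io import (BalanceTerm, CompartmentScaled, Convolution, FixedVector,
                       LabelingDataset, MeasuredMID, MetaboliteBalance,
                       MetabolicNetwork, MIDBalanceSpec, network_from_dict)

__all__ = ["SimulationScenario", "simulate_labeling", "euler_propagate",
           "add_noise", "perturb_boundary", "steady_pool_timeseries",
           "toy5", "mini_cbc"]

#: Slack on the [0, 1] fraction range during propagation.  Compartment-scaled
#: consumption terms make the total-pool balance non-conservative (the
#: approximation is inherited from the compartmentation model), so fractions
#: may legitimately leave the simplex by a small margin.
FRACTION_SLACK = 0.02


@dataclass
class SimulationScenario:
    """Everything needed to generate a ground-truth dataset."""

    network: MetabolicNetwork
    spec: MIDBalanceSpec
    true_fluxes: dict[str, float]
    true_pools: dict[str, float]
    sample_times: np.ndarray
    boundary_reactions: list[str]
    boundary_sd: dict[str, float]
    pool_sd: dict[str, float]
    init_mids: dict[str, np.ndarray] = field(default_factory=dict)
    c_params: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.01
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        v = self.v_star()
        resid = float(np.max(np.abs(self.network.N @ v)))
        if resid > 1e-9 * max(1.0, float(np.max(np.abs(v)))):
            raise ValueError(f"true fluxes violate steady state (|Nv*| = {resid:.2e})")
        if np.any(v < self.network.v_min - 1e-12) or np.any(v > self.network.v_max + 1e-12):
            raise ValueError("true fluxes violate bounds")
        for bal in self.spec.balances:
            x0 = self.initial_mid(bal.metabolite_id)
            if x0.size != bal.n_carbons + 1 or abs(x0.sum() - 1) > 1e-9:
                raise ValueError(f"bad initial MID for {bal.metabolite_id!r}")

    def v_star(self) -> np.ndarray:
        return np.array([self.true_fluxes[r] for r in self.network.reaction_ids])

    def initial_mid(self, metabolite: str) -> np.ndarray:
        if metabolite in self.init_mids:
            return np.asarray(self.init_mids[metabolite], dtype=float)
        n = next(b.n_carbons for b in self.spec.balances
                 if b.metabolite_id == metabolite)
        x0 = np.zeros(n + 1)
        x0[0] = 1.0   # fully unlabeled start
        return x0


def _state_layout(spec: MIDBalanceSpec) -> dict[str, slice]:
    out, pos = {}, 0
    for b in spec.balances:
        out[b.metabolite_id] = slice(pos, pos + b.n_carbons + 1)
        pos += b.n_carbons + 1
    return out


def _rhs_factory(scenario: SimulationScenario):
    spec, net = scenario.spec, scenario.network
    layout = _state_layout(spec)
    missing = spec.measured_metabolites() - set(layout)
    if missing:
        raise ValueError(f"spec references untracked metabolites: {sorted(missing)}; "
                         "the simulator needs dynamics for every measured MID")
    v = {r: scenario.true_fluxes[r] for r in net.reaction_ids}
    pools = scenario.true_pools

    def rhs(t, x):
        lookup = lambda met: x[layout[met]]
        dx = np.zeros_like(x)
        for b in spec.balances:
            acc = np.zeros(b.n_carbons + 1)
            for term in b.terms:
                acc += term.coeff * v[term.reaction_id] * term.source.evaluate(
                    lookup, scenario.c_params)
            dx[layout[b.metabolite_id]] = acc / pools[b.metabolite_id]
        return dx

    return rhs, layout


def _trajectory_to_dataset(scenario: SimulationScenario, times: np.ndarray,
                           X: np.ndarray, layout: Mapping[str, slice]) -> LabelingDataset:
    recs = []
    for met, sl in layout.items():
        for ti, t in enumerate(times):
            for j, f in enumerate(X[ti, sl]):
                recs.append((met, j, float(t), 0, float(f)))
    mids = pd.DataFrame(recs, columns=["metabolite", "isotopologue", "time_s",
                                       "replicate", "fraction"])
    pools = pd.DataFrame({
        "metabolite": list(scenario.true_pools),
        "mean": [scenario.true_pools[m] for m in scenario.true_pools],
        "sd": [scenario.pool_sd.get(m, 0.0) for m in scenario.true_pools]})
    fluxes = pd.DataFrame({
        "reaction": scenario.boundary_reactions,
        "mean": [scenario.true_fluxes[r] for r in scenario.boundary_reactions],
        "sd": [scenario.boundary_sd[r] for r in scenario.boundary_reactions]})
    return LabelingDataset(mids, pools, fluxes)


def simulate_labeling(scenario: SimulationScenario,
                      sample_times: Sequence[float] | None = None,
                      normalize: bool = True,
                      rtol: float = 1e-10, atol: float = 1e-12) -> LabelingDataset:
    """Integrate the labeling ODE exactly and sample it (noise-free)."""
    rhs, layout = _rhs_factory(scenario)
    times = np.asarray(sample_times if sample_times is not None
                       else scenario.sample_times, dtype=float)
    x0 = np.concatenate([scenario.initial_mid(b.metabolite_id)
                         for b in scenario.spec.balances])
    sol = solve_ivp(rhs, (times[0], times[-1]), x0, t_eval=times,
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"labeling integration failed: {sol.message}")
    X = sol.y.T.copy()
    if normalize:
        for sl in layout.values():
            X[:, sl] /= X[:, sl].sum(axis=1, keepdims=True)
    return _trajectory_to_dataset(scenario, times, X, layout)


def euler_propagate(scenario: SimulationScenario,
                    dt: float | None = None) -> LabelingDataset:
    """Generate data satisfying the Forward Euler recursion exactly.

    With ``dt`` unset the recursion steps over the scenario's own sample
    times (variable step widths dt_i); otherwise over the uniform grid
    {t0, t0+dt, ...}.  Fractions leaving [0, 1] by more than a small slack
    indicate step overshoot and raise an error advising a smaller step.
    """
    rhs, layout = _rhs_factory(scenario)
    if dt is None:
        times = scenario.sample_times
    else:
        if dt <= 0:
            raise ValueError("dt must be positive")
        t0, t1 = scenario.sample_times[0], scenario.sample_times[-1]
        times = np.arange(t0, t1 + 0.5 * dt, dt)
    X = np.empty((len(times), sum(sl.stop - sl.start for sl in layout.values())))
    X[0] = np.concatenate([scenario.initial_mid(b.metabolite_id)
                           for b in scenario.spec.balances])
    for i in range(len(times) - 1):
        step = times[i + 1] - times[i]
        X[i + 1] = X[i] + rhs(times[i], X[i]) * step
        if X[i + 1].min() < -FRACTION_SLACK or X[i + 1].max() > 1 + FRACTION_SLACK:
            raise ValueError(
                f"Euler step overshoot at t = {times[i + 1]:g} s; use a smaller dt")
    return _trajectory_to_dataset(scenario, times, X, layout)


def add_noise(dataset: LabelingDataset, noise_sd, n_replicates: int,
              seed: int, renormalize: bool = True) -> LabelingDataset:
    """Replicate the dataset with Gaussian noise on the MID fractions.

    ``noise_sd`` is a scalar SD in fraction units or a per-metabolite
    mapping.  With ``renormalize`` (default, emulating how measured MIDs are
    reported) noisy fractions are clipped to [0, 1] and rescaled to sum 1;
    without it the noise stays exactly Gaussian, which is what calibration
    studies of the chi-square statistic require.
    """
    if np.isscalar(noise_sd) and noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    base = dataset.mids[dataset.mids["replicate"] == dataset.mids["replicate"].iloc[0]]
    frames = []
    for rep in range(n_replicates):
        df = base.copy()
        df["replicate"] = rep
        sd = (df["metabolite"].map(noise_sd) if isinstance(noise_sd, Mapping)
              else float(noise_sd))
        df["fraction"] = df["fraction"] + rng.normal(0.0, 1.0, len(df)) * sd
        frames.append(df)
    mids = pd.concat(frames, ignore_index=True)
    if renormalize:
        mids["fraction"] = mids["fraction"].clip(0.0, 1.0)
        sums = mids.groupby(["metabolite", "time_s", "replicate"])["fraction"].transform("sum")
        mids["fraction"] /= sums
    return LabelingDataset(mids, dataset.pools.copy(),
                           dataset.boundary_fluxes.copy())


def perturb_boundary(dataset: LabelingDataset, seed: int) -> LabelingDataset:
    """Draw measured boundary-flux means from N(true mean, sd)."""
    rng = np.random.default_rng(seed)
    fluxes = dataset.boundary_fluxes.copy()
    fluxes["mean"] = rng.normal(fluxes["mean"], fluxes["sd"])
    return LabelingDataset(dataset.mids.copy(), dataset.pools.copy(), fluxes)


def steady_pool_timeseries(scenario: SimulationScenario, seed: int,
                           n_replicates: int = 3,
                           trend: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Replicate pool-size measurements over the time course.

    ``trend`` maps metabolites to a relative drift per second (0 = steady);
    noise uses each pool's measurement SD.  Output feeds the steady-state
    ANOVA screen.
    """
    rng = np.random.default_rng(seed)
    trend = trend or {}
    recs = []
    for met, mu in scenario.true_pools.items():
        sd = scenario.pool_sd.get(met, 0.05 * mu)
        slope = trend.get(met, 0.0)
        for t in scenario.sample_times:
            level = mu * (1.0 + slope * t)
            for rep in range(n_replicates):
                recs.append((met, float(t), rep, float(rng.normal(level, sd))))
    return pd.DataFrame(recs, columns=["metabolite", "time_s", "replicate",
                                       "pool_size"])


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

SAMPLE_TIMES = np.array([0.0, 5.0, 10.0, 20.0, 40.0])


def toy5(**overrides) -> SimulationScenario:
    """Linear-chain fixture: vin -> A -> B -> C -(x2)-> D -> vexc.

    A, B, C carry one carbon; D is the 2-carbon condensation product of two
    C units.  Both exchange fluxes (vin, vexc) are measured.  All fluxes sit
    on the single steady-state ray of the chain, so the fixture is exactly
    identifiable.
    """
    network = network_from_dict({"reactions": [
        {"id": "v1", "stoich": {"A": -1, "B": 1}},
        {"id": "v2", "stoich": {"B": -1, "C": 1}},
        {"id": "v3", "stoich": {"C": -2, "D": 1}},
        {"id": "vin", "stoich": {"A": 1}},
        {"id": "vexc", "stoich": {"D": -1}},
    ]})
    spec = MIDBalanceSpec([
        MetaboliteBalance("A", 1, [
            BalanceTerm("vin", 1.0, FixedVector([0.0, 1.0])),
            BalanceTerm("v1", -1.0, MeasuredMID("A"))]),
        MetaboliteBalance("B", 1, [
            BalanceTerm("v1", 1.0, MeasuredMID("A")),
            BalanceTerm("v2", -1.0, MeasuredMID("B"))]),
        MetaboliteBalance("C", 1, [
            BalanceTerm("v2", 1.0, MeasuredMID("B")),
            BalanceTerm("v3", -2.0, MeasuredMID("C"))]),
        MetaboliteBalance("D", 2, [
            BalanceTerm("v3", 1.0, Convolution(MeasuredMID("C"), MeasuredMID("C"))),
            BalanceTerm("vexc", -1.0, MeasuredMID("D"))]),
    ])
    defaults = dict(
        network=network, spec=spec,
        true_fluxes={"v1": 2.0, "v2": 2.0, "v3": 1.0, "vin": 2.0, "vexc": 1.0},
        # pool/consumption turnover times all exceed the widest sampling
        # interval (20 s), a prerequisite for the Euler recursion to stay on
        # the simplex
        true_pools={"A": 45.0, "B": 50.0, "C": 60.0, "D": 60.0},
        sample_times=SAMPLE_TIMES.copy(),
        boundary_reactions=["vin", "vexc"],
        boundary_sd={"vin": 0.1, "vexc": 0.05},
        pool_sd={"A": 2.25, "B": 2.5, "C": 3.0, "D": 3.0},
    )
    defaults.update(overrides)
    return SimulationScenario(**defaults)


def mini_cbc(**overrides) -> SimulationScenario:
    """Cyclic carbon-fixation fixture with compartmentation.

    vfix assimilates fully labeled CO2 into a 1-carbon triose-like unit T;
    vcond condenses two T into a hexose-like H; viso (reversible net flux)
    isomerizes H to the compartmented hexose G; vpgm feeds the activated
    sugar U; boundary fluxes vstarch (from U) and vsuc (from the cytosolic
    fraction c_G * G) are measured.  Flux magnitudes are of the order of
    measured carboxylation rates in microalgae (a few nmol gDW^-1 s^-1) and
    all exceed the 1e-6 reporting threshold by >= 5 orders of magnitude.
    """
    network = network_from_dict({"reactions": [
        {"id": "vfix", "stoich": {"T": 1}},
        {"id": "vcond", "stoich": {"T": -2, "H": 1}},
        {"id": "viso", "stoich": {"H": -1, "G": 1}, "reversible": True},
        {"id": "vpgm", "stoich": {"G": -1, "U": 1}},
        {"id": "vstarch", "stoich": {"U": -1}},
        {"id": "vsuc", "stoich": {"G": -1}},
    ]})
    spec = MIDBalanceSpec([
        MetaboliteBalance("T", 1, [
            BalanceTerm("vfix", 1.0, FixedVector([0.0, 1.0])),
            BalanceTerm("vcond", -2.0, MeasuredMID("T"))]),
        MetaboliteBalance("H", 2, [
            BalanceTerm("vcond", 1.0, Convolution(MeasuredMID("T"), MeasuredMID("T"))),
            BalanceTerm("viso", -1.0, MeasuredMID("H"))]),
        MetaboliteBalance("G", 2, [
            BalanceTerm("viso", 1.0, MeasuredMID("H")),
            BalanceTerm("vpgm", -1.0, MeasuredMID("G")),
            BalanceTerm("vsuc", -1.0, CompartmentScaled("c_G", MeasuredMID("G")))]),
        MetaboliteBalance("U", 2, [
            BalanceTerm("vpgm", 1.0, MeasuredMID("G")),
            BalanceTerm("vstarch", -1.0, MeasuredMID("U"))]),
    ])
    defaults = dict(
        network=network, spec=spec,
        true_fluxes={"vfix": 2.4, "vcond": 1.2, "viso": 1.2, "vpgm": 1.0,
                     "vstarch": 1.0, "vsuc": 0.2},
        true_pools={"T": 60.0, "H": 40.0, "G": 300.0, "U": 80.0},
        sample_times=SAMPLE_TIMES.copy(),
        boundary_reactions=["vstarch", "vsuc"],
        boundary_sd={"vstarch": 0.05, "vsuc": 0.02},
        pool_sd={"T": 3.0, "H": 2.0, "G": 15.0, "U": 4.0},
        c_params={"c_G": 0.4},
    )
    defaults.update(overrides)
    return SimulationScenario(**defaults)
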