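"""Input/output layer: networks, MID-balance specifications, labeling datasets.

A flux-estimation run needs three kinds of input:

* a :class:`MetabolicNetwork` — stoichiometry ``N`` (m metabolites x r
  reactions), reversibility flags and flux bounds;
* a :class:`MIDBalanceSpec` — one balance per tracked metabolite stating, for
  every reaction touching its pool, which measured mass-isotopomer
  distribution (MID) multiplies that flux in the labeling ODE;
* a :class:`LabelingDataset` — replicate MID time courses, absolute pool
  sizes (mean +/- SD, nmol gDW^-1) and measured boundary fluxes
  (mean +/- SD, nmol gDW^-1 s^-1).

File formats are deliberately plain: networks and balance specs as JSON, MID
time courses as long-format CSV (metabolite, isotopologue, time_s, replicate,
fraction), pools and boundary fluxes as mean/sd CSV.  Units are fixed to
nmol gDW^-1 (pools), nmol gDW^-1 s^-1 (fluxes) and seconds (time); there is no
unit-conversion layer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_FLUX_BOUND",
    "MID_SUM_TOLERANCE",
    "MetabolicNetwork",
    "MIDVector",
    "SourceExpr",
    "MeasuredMID",
    "Convolution",
    "FixedVector",
    "CompartmentScaled",
    "BalanceTerm",
    "MetaboliteBalance",
    "MIDBalanceSpec",
    "LabelingDataset",
    "SchemaError",
    "load_network",
    "save_network",
    "load_balance_spec",
    "save_balance_spec",
    "load_dataset",
    "save_dataset",
    "load_pool_timeseries",
]

#: Default magnitude of flux bounds, nmol gDW^-1 s^-1.
DEFAULT_FLUX_BOUND = 1.0e6

#: Maximum tolerated deviation of an MID's fraction sum from 1 before a
#: dataset is rejected; smaller deviations are renormalized away on load.
MID_SUM_TOLERANCE = 0.02


class SchemaError(ValueError):
    """Raised when an input file violates the documented schema."""


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


@dataclass
class MetabolicNetwork:
    """Stoichiometric model: ``N`` is (m metabolites x r reactions).

    Irreversible reactions have ``v_min = 0``; reversible ones default to
    ``v_min = -1e6``.  ``v_max`` defaults to ``1e6`` for all reactions.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    N: np.ndarray
    reversible: np.ndarray
    v_min: np.ndarray
    v_max: np.ndarray
    _rank: int | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=float)
        self.reversible = np.asarray(self.reversible, dtype=bool)
        self.v_min = np.asarray(self.v_min, dtype=float)
        self.v_max = np.asarray(self.v_max, dtype=float)
        m, r = len(self.metabolite_ids), len(self.reaction_ids)
        if r == 0:
            raise SchemaError("network has no reactions")
        if m == 0:
            raise SchemaError("network has no metabolites")
        if len(set(self.metabolite_ids)) != m:
            raise SchemaError("duplicate metabolite identifiers")
        if len(set(self.reaction_ids)) != r:
            raise SchemaError("duplicate reaction identifiers")
        if self.N.shape != (m, r):
            raise SchemaError(f"N has shape {self.N.shape}, expected {(m, r)}")
        for arr, name in ((self.reversible, "reversible"), (self.v_min, "v_min"), (self.v_max, "v_max")):
            if arr.shape != (r,):
                raise SchemaError(f"{name} must have one entry per reaction")
        if np.any(self.v_min > self.v_max):
            raise SchemaError("v_min > v_max for some reaction")
        bad = ~self.reversible & (self.v_min < 0)
        if np.any(bad):
            ids = [self.reaction_ids[i] for i in np.flatnonzero(bad)]
            raise SchemaError(f"irreversible reactions with negative v_min: {ids}")

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def rank(self) -> int:
        """Rank of N, computed lazily and cached (row-permutation invariant)."""
        if self._rank is None:
            self._rank = int(np.linalg.matrix_rank(self.N))
        return self._rank

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise KeyError(f"unknown reaction {reaction_id!r}") from None


def _default_bounds(reversible: bool, bounds: Sequence[float] | None) -> tuple[float, float]:
    if bounds is not None:
        lo, hi = float(bounds[0]), float(bounds[1])
        return lo, hi
    return (-DEFAULT_FLUX_BOUND if reversible else 0.0), DEFAULT_FLUX_BOUND


def network_from_dict(doc: Mapping) -> MetabolicNetwork:
    try:
        reactions = doc["reactions"]
    except (KeyError, TypeError):
        raise SchemaError("network document must contain a 'reactions' list")
    if not reactions:
        raise SchemaError("network has no reactions")
    reaction_ids: list[str] = []
    metabolite_ids: list[str] = list(doc.get("metabolites", []))
    stoichs: list[dict] = []
    reversible: list[bool] = []
    vmin: list[float] = []
    vmax: list[float] = []
    for rxn in reactions:
        if "id" not in rxn or "stoich" not in rxn:
            raise SchemaError("each reaction needs 'id' and 'stoich'")
        reaction_ids.append(str(rxn["id"]))
        stoich = {str(k): float(c) for k, c in rxn["stoich"].items()}
        stoichs.append(stoich)
        for met in stoich:
            if met not in metabolite_ids:
                metabolite_ids.append(met)
        rev = bool(rxn.get("reversible", False))
        reversible.append(rev)
        lo, hi = _default_bounds(rev, rxn.get("bounds"))
        vmin.append(lo)
        vmax.append(hi)
    N = np.zeros((len(metabolite_ids), len(reaction_ids)))
    for j, stoich in enumerate(stoichs):
        for met, coeff in stoich.items():
            N[metabolite_ids.index(met), j] = coeff
    return MetabolicNetwork(metabolite_ids, reaction_ids, N, np.array(reversible),
                            np.array(vmin), np.array(vmax))


def load_network(path: str | Path) -> MetabolicNetwork:
    """Read a network from a JSON file (see module docstring for the schema)."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"invalid JSON in {path}: {exc}") from exc
    return network_from_dict(doc)


def save_network(network: MetabolicNetwork, path: str | Path) -> None:
    reactions = []
    for j, rid in enumerate(network.reaction_ids):
        stoich = {network.metabolite_ids[i]: network.N[i, j]
                  for i in np.flatnonzero(network.N[:, j])}
        reactions.append({
            "id": rid,
            "stoich": stoich,
            "reversible": bool(network.reversible[j]),
            "bounds": [network.v_min[j], network.v_max[j]],
        })
    doc = {"metabolites": network.metabolite_ids, "reactions": reactions}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# MID vectors and source expressions
# ---------------------------------------------------------------------------


@dataclass
class MIDVector:
    """Mass isotopomer distribution of one metabolite: fractions M+0 ... M+n."""

    metabolite_id: str
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.ndim != 1 or self.fractions.size < 1:
            raise ValueError("fractions must be a non-empty 1-D vector")

    @property
    def n_carbons(self) -> int:
        return self.fractions.size - 1


class SourceExpr:
    """MID expression appearing in a balance term.

    Subclasses evaluate to an MID vector given a lookup from metabolite id to
    measured fractions and a mapping of compartmentation coefficients.
    """

    def n_states(self, carbons: Mapping[str, int]) -> int:
        raise NotImplementedError

    def evaluate(self, lookup, c_params: Mapping[str, float]) -> np.ndarray:
        raise NotImplementedError

    def measured_metabolites(self) -> set[str]:
        return set()

    def c_param_ids(self) -> set[str]:
        return set()

    def to_dict(self) -> dict:
        raise NotImplementedError


@dataclass
class MeasuredMID(SourceExpr):
    metabolite_id: str

    def n_states(self, carbons):
        if self.metabolite_id not in carbons:
            raise SchemaError(f"no MID data for metabolite {self.metabolite_id!r}")
        return carbons[self.metabolite_id] + 1

    def evaluate(self, lookup, c_params):
        return np.asarray(lookup(self.metabolite_id), dtype=float)

    def measured_metabolites(self):
        return {self.metabolite_id}

    def to_dict(self):
        return {"mid": self.metabolite_id}


@dataclass
class Convolution(SourceExpr):
    """MID of a condensation product: Cauchy product of the precursor MIDs."""

    a: SourceExpr
    b: SourceExpr

    def n_states(self, carbons):
        return self.a.n_states(carbons) + self.b.n_states(carbons) - 1

    def evaluate(self, lookup, c_params):
        return np.convolve(self.a.evaluate(lookup, c_params),
                           self.b.evaluate(lookup, c_params))

    def measured_metabolites(self):
        return self.a.measured_metabolites() | self.b.measured_metabolites()

    def c_param_ids(self):
        return self.a.c_param_ids() | self.b.c_param_ids()

    def to_dict(self):
        return {"conv": [self.a.to_dict(), self.b.to_dict()]}


@dataclass
class FixedVector(SourceExpr):
    """Constant MID, e.g. pure 13CO2 = [0, 1]."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    def n_states(self, carbons):
        return self.values.size

    def evaluate(self, lookup, c_params):
        return self.values

    def to_dict(self):
        return {"fixed": list(self.values)}


@dataclass
class CompartmentScaled(SourceExpr):
    """Cytosolic MID approximated as c times the measured (plastidic) MID."""

    c_param_id: str
    source: SourceExpr

    def n_states(self, carbons):
        return self.source.n_states(carbons)

    def evaluate(self, lookup, c_params):
        if self.c_param_id not in c_params:
            raise KeyError(f"unresolved compartmentation coefficient {self.c_param_id!r}")
        return c_params[self.c_param_id] * self.source.evaluate(lookup, c_params)

    def measured_metabolites(self):
        return self.source.measured_metabolites()

    def c_param_ids(self):
        return {self.c_param_id} | self.source.c_param_ids()

    def to_dict(self):
        return {"scaled": {"c": self.c_param_id, "source": self.source.to_dict()}}


def source_from_dict(doc: Mapping) -> SourceExpr:
    if not isinstance(doc, Mapping) or len(doc) != 1:
        raise SchemaError(f"malformed source expression: {doc!r}")
    (kind, payload), = doc.items()
    if kind == "mid":
        return MeasuredMID(str(payload))
    if kind == "conv":
        if len(payload) != 2:
            raise SchemaError("'conv' takes exactly two child sources")
        return Convolution(source_from_dict(payload[0]), source_from_dict(payload[1]))
    if kind == "fixed":
        return FixedVector(np.asarray(payload, dtype=float))
    if kind == "scaled":
        return CompartmentScaled(str(payload["c"]), source_from_dict(payload["source"]))
    raise SchemaError(f"unknown source kind {kind!r}")


# ---------------------------------------------------------------------------
# Balance specification
# ---------------------------------------------------------------------------


@dataclass
class BalanceTerm:
    """One flux-weighted MID term in a tracked metabolite's labeling balance."""

    reaction_id: str
    coeff: float
    source: SourceExpr


@dataclass
class MetaboliteBalance:
    """Labeling balance of one tracked metabolite (rows M+0 ... M+n)."""

    metabolite_id: str
    n_carbons: int
    terms: list[BalanceTerm]


@dataclass
class MIDBalanceSpec:
    """Declarative description of the matrix S: which measured MIDs, weighted
    by which fluxes, drive each tracked isotopologue's concentration change.

    ``drop_m0`` removes the M+0 row of every tracked metabolite from the
    fitted system (the rows are linearly dependent on M+1..M+n when MIDs are
    normalized; the default keeps them, treating each isotopologue as a
    separate measurement).
    """

    balances: list[MetaboliteBalance]
    drop_m0: bool = False

    @property
    def tracked_metabolites(self) -> list[str]:
        return [b.metabolite_id for b in self.balances]

    def rows(self) -> list[tuple[str, int]]:
        """Tracked (metabolite, isotopologue index) pairs, in fit order."""
        out = []
        j0 = 1 if self.drop_m0 else 0
        for b in self.balances:
            out.extend((b.metabolite_id, j) for j in range(j0, b.n_carbons + 1))
        return out

    @property
    def n_rows(self) -> int:
        return len(self.rows())

    def c_param_ids(self) -> list[str]:
        ids: list[str] = []
        for b in self.balances:
            for t in b.terms:
                for cid in sorted(t.source.c_param_ids()):
                    if cid not in ids:
                        ids.append(cid)
        return ids

    def measured_metabolites(self) -> set[str]:
        mets = set(self.tracked_metabolites)
        for b in self.balances:
            for t in b.terms:
                mets |= t.source.measured_metabolites()
        return mets

    def validate(self, network: MetabolicNetwork,
                 carbons: Mapping[str, int] | None = None) -> None:
        """Cross-check reaction references and source carbon counts.

        ``carbons`` maps every measured metabolite to its carbon count; when
        provided, each term's source must evaluate to an MID of the target's
        length (convolution products included).
        """
        if not self.balances:
            raise SchemaError("balance spec tracks no metabolites")
        seen = set()
        for b in self.balances:
            if b.metabolite_id in seen:
                raise SchemaError(f"metabolite {b.metabolite_id!r} tracked twice")
            seen.add(b.metabolite_id)
            for t in b.terms:
                if t.reaction_id not in network.reaction_ids:
                    raise SchemaError(
                        f"balance of {b.metabolite_id!r} references unknown "
                        f"reaction {t.reaction_id!r}")
                if carbons is not None:
                    n = t.source.n_states(carbons)
                    if n != b.n_carbons + 1:
                        raise SchemaError(
                            f"source of {t.reaction_id!r} in balance of "
                            f"{b.metabolite_id!r} yields {n} isotopologues, "
                            f"expected {b.n_carbons + 1}")


def balance_spec_from_dict(doc: Mapping) -> MIDBalanceSpec:
    try:
        tracked = doc["tracked"]
    except (KeyError, TypeError):
        raise SchemaError("balance spec must contain a 'tracked' list")
    balances = []
    for entry in tracked:
        terms = [BalanceTerm(str(t["reaction"]), float(t["coeff"]),
                             source_from_dict(t["source"]))
                 for t in entry["terms"]]
        balances.append(MetaboliteBalance(str(entry["metabolite"]),
                                          int(entry["n_carbons"]), terms))
    return MIDBalanceSpec(balances, drop_m0=bool(doc.get("drop_m0", False)))


def load_balance_spec(path: str | Path) -> MIDBalanceSpec:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"invalid JSON in {path}: {exc}") from exc
    return balance_spec_from_dict(doc)


def save_balance_spec(spec: MIDBalanceSpec, path: str | Path) -> None:
    doc = {
        "tracked": [
            {
                "metabolite": b.metabolite_id,
                "n_carbons": b.n_carbons,
                "terms": [{"reaction": t.reaction_id, "coeff": t.coeff,
                           "source": t.source.to_dict()} for t in b.terms],
            }
            for b in spec.balances
        ],
        "drop_m0": spec.drop_m0,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# Labeling dataset
# ---------------------------------------------------------------------------


@dataclass
class LabelingDataset:
    """MID time courses with replicate structure, pools and boundary fluxes.

    ``mids`` is a long-format table with columns (metabolite, isotopologue,
    time_s, replicate, fraction).  ``pools`` and ``boundary_fluxes`` have
    columns (metabolite|reaction, mean, sd).
    """

    mids: pd.DataFrame
    pools: pd.DataFrame
    boundary_fluxes: pd.DataFrame
    _mean_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        required = {"metabolite", "isotopologue", "time_s", "replicate", "fraction"}
        missing = required - set(self.mids.columns)
        if missing:
            raise SchemaError(f"MID table missing columns: {sorted(missing)}")
        if (self.pools["sd"] < 0).any():
            raise SchemaError("negative pool SD")
        if len(self.time_points) < 1:
            raise SchemaError("dataset has no time points")
        if not np.all(np.diff(self.time_points) > 0):
            raise SchemaError("time points must be strictly increasing")

    # -- basic structure ----------------------------------------------------

    @property
    def time_points(self) -> np.ndarray:
        return np.array(sorted(self.mids["time_s"].unique()), dtype=float)

    @property
    def intervals(self) -> np.ndarray:
        """Forward differences Delta t_i between consecutive time points."""
        return np.diff(self.time_points)

    @property
    def metabolites(self) -> list[str]:
        return sorted(self.mids["metabolite"].unique())

    @property
    def n_replicates(self) -> int:
        return int(self.mids["replicate"].nunique())

    def n_carbons(self, metabolite: str) -> int:
        sub = self.mids.loc[self.mids["metabolite"] == metabolite, "isotopologue"]
        if sub.empty:
            raise KeyError(f"no MID data for metabolite {metabolite!r}")
        return int(sub.max())

    @property
    def carbon_counts(self) -> dict[str, int]:
        return {m: self.n_carbons(m) for m in self.metabolites}

    # -- accessors ----------------------------------------------------------

    def _mean_array(self, metabolite: str) -> np.ndarray:
        """Replicate-mean fractions, shape (n_times, n_carbons + 1)."""
        if metabolite not in self._mean_cache:
            sub = self.mids[self.mids["metabolite"] == metabolite]
            if sub.empty:
                raise KeyError(f"no MID data for metabolite {metabolite!r}")
            piv = sub.pivot_table(index="time_s", columns="isotopologue",
                                  values="fraction", aggfunc="mean")
            piv = piv.reindex(index=self.time_points,
                              columns=range(self.n_carbons(metabolite) + 1))
            if piv.isna().any().any():
                raise SchemaError(
                    f"metabolite {metabolite!r} lacks MID data at some time point")
            self._mean_cache[metabolite] = piv.to_numpy(dtype=float)
        return self._mean_cache[metabolite]

    def mean_mid(self, metabolite: str, time_index: int) -> np.ndarray:
        """Replicate-mean MID vector of ``metabolite`` at time index ``time_index``."""
        return self._mean_array(metabolite)[time_index]

    def replicate_sd(self, metabolite: str) -> np.ndarray:
        """Across-replicate SD of fractions, shape (n_times, n_carbons + 1).

        Zero where only one replicate exists.
        """
        sub = self.mids[self.mids["metabolite"] == metabolite]
        piv = sub.pivot_table(index="time_s", columns="isotopologue",
                              values="fraction", aggfunc=lambda v: np.std(v, ddof=1) if len(v) > 1 else 0.0)
        piv = piv.reindex(index=self.time_points,
                          columns=range(self.n_carbons(metabolite) + 1))
        return piv.fillna(0.0).to_numpy(dtype=float)

    def pool(self, metabolite: str) -> tuple[float, float]:
        row = self.pools[self.pools["metabolite"] == metabolite]
        if row.empty:
            raise KeyError(f"no pool measurement for metabolite {metabolite!r}")
        return float(row["mean"].iloc[0]), float(row["sd"].iloc[0])

    def boundary(self, reaction: str) -> tuple[float, float]:
        row = self.boundary_fluxes[self.boundary_fluxes["reaction"] == reaction]
        if row.empty:
            raise KeyError(f"no boundary-flux measurement for reaction {reaction!r}")
        return float(row["mean"].iloc[0]), float(row["sd"].iloc[0])

    # -- transforms ---------------------------------------------------------

    def mask_times(self, keep: Iterable[float]) -> "LabelingDataset":
        """Restrict the dataset to the given subset of time points."""
        keep = sorted(float(t) for t in keep)
        present = set(self.time_points)
        absent = [t for t in keep if t not in present]
        if absent:
            raise SchemaError(f"mask requests absent time points: {absent}")
        sub = self.mids[self.mids["time_s"].isin(keep)].reset_index(drop=True)
        return LabelingDataset(sub, self.pools.copy(), self.boundary_fluxes.copy())

    def validate_fractions(self, tolerance: float = MID_SUM_TOLERANCE,
                           renormalize: bool = True) -> "LabelingDataset":
        """Check and optionally renormalize MID sums per (metabolite, time, replicate)."""
        mids = self.mids.copy()
        if (mids["fraction"] < -tolerance).any() or (mids["fraction"] > 1 + tolerance).any():
            raise SchemaError("MID fractions outside [0, 1] beyond tolerance")
        sums = mids.groupby(["metabolite", "time_s", "replicate"])["fraction"].transform("sum")
        if (np.abs(sums - 1.0) > tolerance).any():
            worst = float(np.abs(sums - 1.0).max())
            raise SchemaError(
                f"MID fractions do not sum to 1 within {tolerance} (worst |sum-1| = {worst:.4f})")
        if renormalize:
            mids["fraction"] = mids["fraction"].clip(lower=0.0) / sums
        return LabelingDataset(mids, self.pools.copy(), self.boundary_fluxes.copy())


def load_dataset(mid_path: str | Path, pool_path: str | Path,
                 flux_path: str | Path,
                 mask: Iterable[float] | None = None) -> LabelingDataset:
    """Load MID/pool/boundary-flux CSVs into a validated :class:`LabelingDataset`.

    MID fractions are renormalized to sum 1 per (metabolite, time, replicate);
    deviations beyond :data:`MID_SUM_TOLERANCE` are an error.  ``mask`` keeps
    only the listed time points (e.g. dropping a late time point at which
    metabolic steady state no longer holds).
    """
    mids = pd.read_csv(mid_path)
    pools = pd.read_csv(pool_path)
    fluxes = pd.read_csv(flux_path)
    for df, cols, name in ((pools, {"metabolite", "mean", "sd"}, "pool"),
                           (fluxes, {"reaction", "mean", "sd"}, "boundary-flux")):
        missing = cols - set(df.columns)
        if missing:
            raise SchemaError(f"{name} table missing columns: {sorted(missing)}")
    ds = LabelingDataset(mids, pools, fluxes)
    if ds.n_replicates == 1:
        warnings.warn("dataset has a single replicate; measurement SDs are "
                      "undefined and a sigma override will be required",
                      stacklevel=2)
    ds = ds.validate_fractions()
    if mask is not None:
        ds = ds.mask_times(mask)
    return ds


def save_dataset(dataset: LabelingDataset, mid_path: str | Path,
                 pool_path: str | Path, flux_path: str | Path) -> None:
    dataset.mids.to_csv(mid_path, index=False)
    dataset.pools.to_csv(pool_path, index=False)
    dataset.boundary_fluxes.to_csv(flux_path, index=False)


def load_pool_timeseries(path: str | Path) -> pd.DataFrame:
    """Read a replicate pool-size time course (metabolite, time_s, replicate,
    pool_size) used by the metabolic-steady-state ANOVA screen."""
    df = pd.read_csv(path)
    missing = {"metabolite", "time_s", "replicate", "pool_size"} - set(df.columns)
    if missing:
        raise SchemaError(f"pool time-series table missing columns: {sorted(missing)}")
    return df
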