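"""Long-format clustered functional data on a regular grid.

One row per (cluster i, longitudinal observation j, functional point s).
Within a cluster the canonical stacking order is s-major: the flattened
outcome vector Y_i = (Y_i(s_1)^T, ..., Y_i(s_L)^T)^T concatenates, for each
grid point, the outcome across longitudinal observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .families import get_family

__all__ = ["FunctionalDataset", "read_dataset", "write_fit", "read_fit"]


@dataclass
class FunctionalDataset:
    """Clustered longitudinal functional observations on a shared regular grid.

    Attributes
    ----------
    grid : (L,) strictly increasing functional-domain locations (original units).
    cluster_ids : (N,) unique cluster identifiers, in row-group order.
    n : (N,) longitudinal observations per cluster.
    Y : (M, L) outcomes, M = sum(n); rows grouped by cluster, j ascending.
    X : (M, q, L) covariate values (scalar covariates are constant over the
        last axis; concurrent functional covariates vary with it).
    family : outcome family tag ("gaussian", "binomial", "poisson").
    covariate_names : q column names.
    """

    grid: np.ndarray
    cluster_ids: np.ndarray
    n: np.ndarray
    Y: np.ndarray
    X: np.ndarray
    family: str
    covariate_names: list = field(default_factory=list)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        self.Y = np.asarray(self.Y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 2:  # scalar covariates: broadcast over the grid
            self.X = np.repeat(self.X[:, :, None], self.L, axis=2)
        self.validate()

    # -- shapes -----------------------------------------------------------
    @property
    def N(self) -> int:
        return len(self.cluster_ids)

    @property
    def L(self) -> int:
        return self.grid.shape[0]

    @property
    def q(self) -> int:
        return self.X.shape[1]

    @property
    def offsets(self) -> np.ndarray:
        """(N+1,) row offsets delimiting each cluster's block in Y and X."""
        return np.concatenate([[0], np.cumsum(self.n)])

    @property
    def grid01(self) -> np.ndarray:
        """Grid rescaled to [0, 1] (used internally for spline conditioning)."""
        g = self.grid
        return (g - g[0]) / (g[-1] - g[0])

    def validate(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        M = int(self.n.sum())
        if self.Y.shape != (M, self.L):
            raise ValueError(f"Y has shape {self.Y.shape}, expected {(M, self.L)}")
        if self.X.shape[0] != M or self.X.shape[2] != self.L:
            raise ValueError(f"X has shape {self.X.shape}, expected ({M}, q, {self.L})")
        if not np.all(np.isfinite(self.Y)):
            raise ValueError("non-finite outcome values")
        get_family(self.family).validate_outcome(self.Y)

    # -- access -----------------------------------------------------------
    def cluster_rows(self, i: int) -> slice:
        off = self.offsets
        return slice(off[i], off[i + 1])

    def stacked_outcome(self, i: int) -> np.ndarray:
        """Y_i = (Y_i(s_1)^T, ..., Y_i(s_L)^T)^T, length n_i * L (s-major)."""
        return self.Y[self.cluster_rows(i)].T.ravel()

    def covariate_tensor(self) -> np.ndarray:
        """(M, q+1, L) covariates with a leading intercept slot of ones."""
        M = self.Y.shape[0]
        C = np.empty((M, self.q + 1, self.L))
        C[:, 0, :] = 1.0
        C[:, 1:, :] = self.X
        return C

    def to_long(self) -> pd.DataFrame:
        """Long-format frame: one row per (cluster, obs j, grid point)."""
        M, L = self.Y.shape
        cl = np.repeat(self.cluster_ids, self.n)
        j = np.concatenate([np.arange(1, ni + 1) for ni in self.n])
        rows = {
            "cluster": np.repeat(cl, L),
            "obs": np.repeat(j, L),
            "s": np.tile(self.grid, M),
            "y": self.Y.ravel(),
        }
        names = self.covariate_names or [f"x{r + 1}" for r in range(self.q)]
        for r, name in enumerate(names):
            rows[name] = self.X[:, r, :].ravel()
        return pd.DataFrame(rows)

    @classmethod
    def from_long(cls, df: pd.DataFrame, family: str,
                  cluster: str = "cluster", obs: str = "obs", arg: str = "s",
                  outcome: str = "y", covariates=None) -> "FunctionalDataset":
        """Build a dataset from a long-format frame, validating the grid.

        Every (cluster, obs) pair must contain exactly one row per grid point
        (regular, evenly observed grid); violations raise naming the cluster.
        """
        if covariates is None:
            covariates = [c for c in df.columns
                          if c not in (cluster, obs, arg, outcome)]
        for col in (cluster, obs, arg, outcome, *covariates):
            if col not in df.columns:
                raise KeyError(f"required column {col!r} not found in input")
        df = df.sort_values([cluster, obs, arg], kind="mergesort")
        grid = np.unique(df[arg].to_numpy(dtype=float))
        L = grid.shape[0]
        cluster_ids, n_rows = np.unique(df[cluster].to_numpy(), return_counts=True)
        # preserve first-appearance order of clusters
        first = df.groupby(cluster, sort=False).ngroup().to_numpy()
        order_ids = df[cluster].to_numpy()[np.unique(first, return_index=True)[1]]
        id_order = {c: k for k, c in enumerate(order_ids)}
        perm = np.argsort([id_order[c] for c in cluster_ids], kind="mergesort")
        cluster_ids, n_rows = cluster_ids[perm], n_rows[perm]

        n = np.empty(len(cluster_ids), dtype=int)
        Y_parts, X_parts = [], []
        for k, cid in enumerate(cluster_ids):
            sub = df[df[cluster] == cid]
            n_i, rem = divmod(len(sub), L)
            obs_counts = sub.groupby(obs)[arg].count()
            if rem or (obs_counts != L).any():
                raise ValueError(
                    f"ragged grid: cluster {cid!r} does not have exactly "
                    f"{L} grid points for every observation"
                )
            svals = sub[arg].to_numpy(dtype=float).reshape(n_i, L)
            if not np.allclose(svals, grid[None, :]):
                raise ValueError(f"ragged grid: cluster {cid!r} grid differs")
            n[k] = n_i
            Y_parts.append(sub[outcome].to_numpy(dtype=float).reshape(n_i, L))
            X_parts.append(np.stack(
                [sub[c].to_numpy(dtype=float).reshape(n_i, L) for c in covariates],
                axis=1) if covariates else np.empty((n_i, 0, L)))
        return cls(grid=grid, cluster_ids=cluster_ids, n=n,
                   Y=np.concatenate(Y_parts), X=np.concatenate(X_parts),
                   family=family, covariate_names=list(covariates))


def read_dataset(path, family: str, schema=None) -> FunctionalDataset:
    """Read a delimited long-format file (CSV/TSV by extension) into a dataset.

    ``schema`` maps roles to column names, e.g.
    ``{"cluster": "id", "obs": "trial", "arg": "time", "outcome": "y",
    "covariates": ["x1", "x2"]}``; missing roles use the defaults.
    """
    schema = dict(schema or {})
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    return FunctionalDataset.from_long(
        df, family=family,
        cluster=schema.get("cluster", "cluster"),
        obs=schema.get("obs", "obs"),
        arg=schema.get("arg", "s"),
        outcome=schema.get("outcome", "y"),
        covariates=schema.get("covariates"),
    )


def write_fit(results, path) -> None:
    """Write a coefficient table: one row per (coefficient, grid point).

    Columns: coefficient, s, estimate, se, pointwise lower/upper and (when
    present) joint lower/upper. A metadata comment line records whether joint
    bands are included. Values round-trip losslessly through :func:`read_fit`.
    """
    frame = results.to_frame()
    has_joint = "joint_lower" in frame.columns
    with open(path, "w") as fh:
        fh.write(f"# fgee coefficient table; joint_bands={str(has_joint).lower()}\n")
        frame.to_csv(fh, index=False)


def read_fit(path) -> pd.DataFrame:
    """Read back a coefficient table written by :func:`write_fit`."""
    return pd.read_csv(path, comment="#", float_precision="round_trip")
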