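"""Static functional connectivity: regularized partial correlations.

Session-averaged coupling between node time series is estimated as the
partial correlation derived from an L1-penalized inverse-covariance
(graphical lasso) fit on standardized series, then Fisher z-transformed.
Edges are stored in a canonical 1-based row-major upper-triangle order:
(1,2), (1,3), ..., (1,n), (2,3), ..., (n-1,n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.covariance import GraphicalLasso

__all__ = [
    "EdgeVector",
    "n_edges",
    "edge_index",
    "index_to_pair",
    "edge_pairs",
    "edge_columns",
    "fisher_z",
    "partial_correlation_matrix",
    "regularized_partial_correlation",
    "sfc_cohort",
]


def n_edges(n_nodes: int) -> int:
    """Number of unique node pairs, n(n-1)/2 (325 for 26 nodes)."""
    return n_nodes * (n_nodes - 1) // 2


def edge_index(i: int, j: int, n: int) -> int:
    """1-based canonical index of the node pair (i, j), 1 <= i < j <= n."""
    if not (1 <= i < j <= n):
        raise ValueError(f"need 1 <= i < j <= n, got (i={i}, j={j}, n={n})")
    return (i - 1) * (2 * n - i) // 2 + (j - i)


def index_to_pair(e: int, n: int) -> tuple[int, int]:
    """Inverse of :func:`edge_index`: the node pair of 1-based edge ``e``."""
    m = n_edges(n)
    if not (1 <= e <= m):
        raise ValueError(f"edge index {e} out of range 1..{m} for n={n}")
    # row i is the largest i with cumulative count before row i < e
    rem = e
    for i in range(1, n):
        row = n - i
        if rem <= row:
            return i, i + rem
        rem -= row
    raise AssertionError("unreachable")


def edge_pairs(n: int) -> np.ndarray:
    """All node pairs in canonical order, as an (n_edges, 2) 1-based array."""
    iu, ju = np.triu_indices(n, k=1)
    return np.column_stack([iu + 1, ju + 1])


def edge_columns(n: int) -> list[str]:
    """Column names ``edge_0001 ..`` for an edge matrix with n nodes."""
    return [f"edge_{e:04d}" for e in range(1, n_edges(n) + 1)]


@dataclass
class EdgeVector:
    """Edge-indexed values in canonical upper-triangle order."""

    values: np.ndarray
    metric: str  # "sfc_z" | "dfc_cv" | ...
    n_nodes: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != n_edges(self.n_nodes):
            raise ValueError(
                f"edge vector for {self.n_nodes} nodes must have length "
                f"{n_edges(self.n_nodes)}, got shape {self.values.shape}"
            )

    def __len__(self) -> int:
        return len(self.values)

    def as_matrix(self, diagonal: float = np.nan) -> np.ndarray:
        """Symmetric node x node matrix view of the edge vector."""
        mat = np.full((self.n_nodes, self.n_nodes), diagonal)
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        mat[iu, ju] = self.values
        mat[ju, iu] = self.values
        return mat


def fisher_z(r):
    """Fisher z-transform, atanh(r); rejects |r| >= 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("Fisher z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def _precision_to_partial(precision: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(precision))
    partial = -precision / np.outer(d, d)
    np.fill_diagonal(partial, 1.0)
    return partial


def partial_correlation_matrix(series: np.ndarray, lam: float = 0.1,
                               standardize: bool = True) -> np.ndarray:
    """Partial-correlation matrix of a node x time series matrix.

    ``lam`` is the L1 penalty on the precision matrix (graphical lasso);
    ``lam = 0`` uses the unpenalized sample-precision closed form.  Series
    are standardized first so the penalty is scale-free.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be a node x time matrix")
    n_nodes, n_time = series.shape
    if lam < 0:
        raise ValueError("penalty must be nonnegative")
    if n_time <= n_nodes:
        warnings.warn(
            f"only {n_time} timepoints for {n_nodes} nodes; the covariance "
            "estimate is ill-conditioned",
            stacklevel=2,
        )
    x = series.T  # samples x features
    if standardize:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant node series; cannot standardize")
        x = (x - x.mean(axis=0)) / sd
    if lam == 0:
        cov = np.cov(x, rowvar=False)
        try:
            precision = np.linalg.inv(cov)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "sample covariance is singular at lambda = 0; "
                "increase the penalty or the series length"
            ) from exc
    else:
        model = GraphicalLasso(alpha=lam, assume_centered=False, max_iter=200)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(x)
        except FloatingPointError as exc:
            raise RuntimeError(
                f"graphical lasso did not converge at penalty {lam}"
            ) from exc
        precision = model.precision_
    return _precision_to_partial(precision)


def regularized_partial_correlation(series: np.ndarray, lam: float = 0.1) -> EdgeVector:
    """Canonical edge vector of regularized partial correlations."""
    partial = partial_correlation_matrix(series, lam=lam)
    n = partial.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    values = np.clip(partial[iu, ju], -1.0, 1.0)
    return EdgeVector(values=values, metric="partial_r", n_nodes=n)


def sfc_cohort(panels, lam: float = 0.1) -> pd.DataFrame:
    """Subject x edge matrix of Fisher-z regularized partial correlations.

    Rows are indexed by subject id, columns by canonical edge labels
    (``edge_0001`` ...); for 26-node panels there are 325 columns.
    """
    if not panels:
        raise ValueError("no panels given")
    n = panels[0].n_nodes
    rows = {}
    for panel in panels:
        if panel.n_nodes != n:
            raise ValueError(
                f"panel {panel.subject_id} has {panel.n_nodes} nodes, expected {n}"
            )
        r = regularized_partial_correlation(panel.values, lam=lam).values
        # guard atanh blowup on |r| -> 1 from near-singular fits
        r = np.clip(r, -0.999999, 0.999999)
        rows[panel.subject_id] = fisher_z(r)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=edge_columns(n))
    df.index.name = "subject_id"
    return df
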