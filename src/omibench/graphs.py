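"""Sample-similarity graphs: truncated-correlation weights and Laplacians.

Each omics source yields a sample x sample weight matrix W whose entry
w_ij is the Pearson (or Spearman) correlation between the feature profiles
of samples i and j, truncated at zero — edge weights must be non-negative.
The diagonal is forced to 0 so that self-similarity does not dominate the
degrees. The graph Laplacian is L = D - W with D = diag(row sums of W).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .core import FeatureMatrix


@dataclass
class WeightMatrix:
    """Non-negative sample-affinity matrix with zero diagonal."""

    W: np.ndarray
    symmetric: bool = True
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n, m = self.W.shape
        if n != m:
            raise ValueError("weight matrix must be square")
        if (self.W < 0).any():
            raise ValueError("edge weights must be non-negative")
        if np.abs(np.diag(self.W)).max(initial=0.0) > 0:
            raise ValueError("weight matrix diagonal must be zero")
        if self.symmetric and not np.array_equal(self.W, self.W.T):
            raise ValueError("symmetric flag set but W != W^T")

    @property
    def n(self) -> int:
        return self.W.shape[0]

    def restrict(self, rows: np.ndarray) -> "WeightMatrix":
        rows = np.asarray(rows, dtype=int)
        ids = [self.sample_ids[i] for i in rows] if self.sample_ids else None
        return WeightMatrix(self.W[np.ix_(rows, rows)], self.symmetric, ids)

    def to_edge_list(self):
        """Three-column (i, j, weight) array of the nonzero edges."""
        i, j = np.nonzero(self.W)
        return np.column_stack([i, j, self.W[i, j]])


@dataclass
class LaplacianMatrix:
    """L = D - W for a weight matrix (D = diagonal of row sums)."""

    L: np.ndarray
    weights: WeightMatrix | None = None

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        if self.L.shape[0] != self.L.shape[1]:
            raise ValueError("Laplacian must be square")

    @property
    def n(self) -> int:
        return self.L.shape[0]


def correlation_weights(
    X: FeatureMatrix | np.ndarray,
    method: Literal["pearson", "spearman"] = "pearson",
) -> WeightMatrix:
    """Pairwise sample correlation, negatives zeroed, diagonal zeroed.

    Correlations are computed between the feature profiles of sample pairs;
    a sample with a zero-variance profile gets all-zero weights (with a
    warning) rather than NaNs.
    """
    V = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    ids = X.sample_ids if isinstance(X, FeatureMatrix) else None
    if V.shape[1] < 2:
        raise ValueError("correlation weights need at least 2 features per sample")
    if method == "spearman":
        V = stats.rankdata(V, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    centred = V - V.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    flat = norms == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} sample(s) have constant profiles; their edges are 0",
            stacklevel=2,
        )
    safe = np.where(flat, 1.0, norms)
    C = (centred / safe[:, None]) @ (centred / safe[:, None]).T
    C[flat, :] = 0.0
    C[:, flat] = 0.0
    W = np.clip(C, 0.0, None)
    np.fill_diagonal(W, 0.0)
    W = (W + W.T) / 2.0  # exact symmetry against fp noise
    return WeightMatrix(W, symmetric=True, sample_ids=list(ids) if ids else None)


def laplacian(W: WeightMatrix | np.ndarray) -> LaplacianMatrix:
    """Graph Laplacian L = D - W; PSD for symmetric W."""
    wm = W if isinstance(W, WeightMatrix) else WeightMatrix(np.asarray(W, dtype=float), symmetric=False)
    L = np.diag(wm.W.sum(axis=1)) - wm.W
    return LaplacianMatrix(L, wm)
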