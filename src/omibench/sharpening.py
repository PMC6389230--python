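"""Graph sharpening: directed edge removal before label propagation.

Reading w_ij as the edge strength from node j to node i, sharpening
removes (i) edges from unlabelled nodes into labelled nodes and (ii) edges
between oppositely labelled nodes, leaving an asymmetric, sparser weight
matrix. Information flowing out of labelled nodes to same-label or
unlabelled nodes is preserved. With asymmetric Laplacians L_k the
multi-network solution becomes

    f = [I + 1/2 sum_k alpha_k (L_k + L_k^T)]^{-1} y,

i.e. the usual solution on the symmetrised Laplacians, and the network
weights alpha are optimised exactly as in the symmetric case with
L_k replaced by (L_k + L_k^T)/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LabelVector
from .graphs import LaplacianMatrix, WeightMatrix, laplacian
from .gssl import GraphSSLModel, solve_multi


@dataclass
class SharpenedGraph:
    """Directed weight matrix after sharpening, plus its parent."""

    W_directed: WeightMatrix
    parent: WeightMatrix


def sharpen(W: WeightMatrix, y: LabelVector | np.ndarray) -> SharpenedGraph:
    """Zero w_ij when (i labelled, j unlabelled) or labels(i, j) are opposite."""
    if not W.symmetric:
        raise ValueError("sharpening expects a symmetric parent weight matrix")
    yv = y.labels if isinstance(y, LabelVector) else np.asarray(y)
    if len(yv) != W.n:
        raise ValueError("label vector length does not match weight matrix size")
    Wd = W.W.copy()
    labelled = yv != 0
    # receiver i labelled, sender j unlabelled
    Wd[np.ix_(labelled, ~labelled)] = 0.0
    opposite = np.outer(yv, yv) < 0
    Wd[opposite] = 0.0
    return SharpenedGraph(
        WeightMatrix(Wd, symmetric=False, sample_ids=W.sample_ids), parent=W
    )


def sharpened_laplacian(g: SharpenedGraph) -> LaplacianMatrix:
    return laplacian(g.W_directed)


def solve_sharpened(Ls: list, y, c: float, **kwargs) -> GraphSSLModel:
    """Multi-network solve on (possibly asymmetric) sharpened Laplacians.

    Delegates to the symmetric optimiser, which already works on the
    symmetrised part (L_k + L_k^T)/2 of every Laplacian — for symmetric
    inputs this is exactly the unsharpened solution.
    """
    return solve_multi(Ls, y, c, **kwargs)
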