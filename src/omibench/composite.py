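"""Composite association network: regression-weighted network integration.

Instead of solving a convex program for the per-source network weights,
regress the vectorised source weight matrices onto a label-derived target
network T over the labelled (training) nodes:

    min_alpha || Omega alpha - vec(T) ||^2,
    Omega = [1, vec(W_1), ..., vec(W_m)],

solved by the normal equations. The fitted bias alpha_0 is reported but
discarded when combining; negative source weights are set to zero, and if
every source weight is <= 0 the uniform fallback alpha_i = 1/m is used.
The composite matrix W-bar = sum_i alpha_i W_i (over all nodes) then feeds
single-network label propagation with c fixed to 1 and the median cut-off.

T assigns one of three values by label pair. The default follows the
printed three-level scheme: (n+/n)^2 for negative-negative pairs,
(n-/n)^2 for positive-positive pairs and +n+n-/n^2 for mixed pairs.
``convention="attraction"`` instead rewards same-label pairs and penalises
mixed pairs ((n-/n)^2 pos-pos, (n+/n)^2 neg-neg, -n+n-/n^2 mixed), which
is the variant under which the regression weights track source
informativeness; see docs/methods.md for why the printed scheme carries no
signal for balanced classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import linalg

from .core import LabelVector, MultiOmicsStudy, PredictionResult
from .graphs import WeightMatrix, laplacian
from .gssl import GraphSSLModel, median_cutoff_classify, solve_single

TargetConvention = Literal["printed", "attraction"]


@dataclass
class TargetNetwork:
    T: np.ndarray
    n_pos: int
    n_neg: int


@dataclass
class CompositeWeights:
    alpha: np.ndarray  # per-source weights, >= 0 after the sign rules
    alpha0: float  # fitted bias, reported but not used in combination
    fallback_used: bool
    alpha_raw: np.ndarray | None = None  # fitted weights before the sign rules


def target_network(
    y_train: LabelVector | np.ndarray, convention: TargetConvention = "printed"
) -> TargetNetwork:
    """Three-valued pairwise target matrix over labelled nodes."""
    yv = y_train.labels if isinstance(y_train, LabelVector) else np.asarray(y_train)
    yv = yv[yv != 0]
    n_pos = int((yv == 1).sum())
    n_neg = int((yv == -1).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("target network needs labelled nodes of both classes")
    n = n_pos + n_neg
    if convention == "printed":
        v_pospos = (n_neg / n) ** 2
        v_negneg = (n_pos / n) ** 2
        v_mixed = n_pos * n_neg / n**2
    elif convention == "attraction":
        v_pospos = (n_neg / n) ** 2
        v_negneg = (n_pos / n) ** 2
        v_mixed = -n_pos * n_neg / n**2
    else:
        raise ValueError(f"unknown target convention {convention!r}")
    pos = yv == 1
    T = np.where(
        np.outer(pos, pos),
        v_pospos,
        np.where(np.outer(~pos, ~pos), v_negneg, v_mixed),
    )
    return TargetNetwork(T, n_pos, n_neg)


def fit_weights(
    Ws: list[WeightMatrix | np.ndarray],
    T: TargetNetwork | np.ndarray,
    ridge: float = 1e-8,
) -> CompositeWeights:
    """Least-squares source weights with bias, sign rules and 1/m fallback.

    vec() stacks the full symmetric matrix (both triangles, diagonal
    included). A singular normal matrix (collinear sources) is handled by a
    ridge-regularised solve with a warning.
    """
    Tm = T.T if isinstance(T, TargetNetwork) else np.asarray(T, dtype=float)
    m = len(Ws)
    if m < 1:
        raise ValueError("need at least one source network")
    cols = [np.ones(Tm.size)]
    for W in Ws:
        Wm = W.W if isinstance(W, WeightMatrix) else np.asarray(W, dtype=float)
        if Wm.shape != Tm.shape:
            raise ValueError("source and target networks are not conformable")
        cols.append(Wm.ravel())
    Omega = np.column_stack(cols)
    G = Omega.T @ Omega
    b = Omega.T @ Tm.ravel()
    try:
        coef = linalg.solve(G, b, assume_a="sym")
        if not np.all(np.isfinite(coef)):
            raise linalg.LinAlgError("non-finite solution")
    except linalg.LinAlgError:
        coef = None
    if coef is None or np.linalg.cond(G) > 1e12:
        warnings.warn(
            "singular normal equations (collinear source networks); "
            f"applying ridge regularisation lambda={ridge}",
            stacklevel=2,
        )
        coef = linalg.solve(G + ridge * np.eye(m + 1), b, assume_a="sym")
    alpha0, alpha_raw = float(coef[0]), coef[1:]
    if np.all(alpha_raw <= 0):
        return CompositeWeights(np.full(m, 1.0 / m), alpha0, True, alpha_raw)
    return CompositeWeights(np.clip(alpha_raw, 0.0, None), alpha0, False, alpha_raw)


def combine(Ws: list[WeightMatrix], alpha: np.ndarray) -> WeightMatrix:
    """W-bar = sum_i alpha_i W_i (alpha >= 0 keeps it a valid weight matrix)."""
    Wbar = np.zeros_like(Ws[0].W)
    for a, W in zip(alpha, Ws):
        Wbar += a * W.W
    return WeightMatrix(Wbar, symmetric=all(W.symmetric for W in Ws), sample_ids=Ws[0].sample_ids)


def can_fit_predict(
    Ws: list[WeightMatrix],
    y: LabelVector,
    convention: TargetConvention = "printed",
    c: float = 1.0,
) -> tuple[GraphSSLModel, PredictionResult, CompositeWeights]:
    """Full composite-association-network classifier on a transductive graph.

    ``Ws`` are full-study weight matrices; the regression is fit on the
    labelled-node submatrices only (the target is undefined elsewhere), the
    fitted alpha then combines the full matrices, and scores are propagated
    with c = 1 (the method's fixed setting) and classified by median cut-off.
    """
    yv = y.labels if isinstance(y, LabelVector) else np.asarray(y)
    lab = np.flatnonzero(yv != 0)
    T = target_network(yv[lab], convention=convention)
    weights = fit_weights([W.restrict(lab) for W in Ws], T)
    Wbar = combine(Ws, weights.alpha)
    model = solve_single(laplacian(Wbar), yv.astype(float), c=c)
    pred = median_cutoff_classify(model.f, yv)
    return model, pred, weights
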