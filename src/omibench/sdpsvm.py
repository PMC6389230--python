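"""Multiple-kernel 1-norm soft-margin SVM via a QCQP dual.

The per-source kernels K_1..K_m are combined as K = sum_i mu_i K_i with
mu_i >= 0 learned jointly with the SVM dual. With the trace budget
trace(sum mu_i K_i) = c the saddle problem reduces to the quadratically
constrained quadratic program

    max_{alpha, t}  2 alpha^T e - c t
    s.t.            t >= (1/r_i) alpha^T diag(y) K_i diag(y) alpha,
                    r_i = trace(K_i),
                    alpha^T y = 0,   0 <= alpha <= C,

solved here by an interior-point method (scipy trust-constr) with analytic
gradients and Hessians. The kernel weights mu_i are the Lagrange
multipliers of the quadratic constraints; KKT stationarity in t gives
sum_i mu_i r_i = c, so the trace budget is automatically met. c defaults
to the training-set size, which makes the normalised weights sum to one.

Decision values use the standard dual expansion
f(x) = sum_i alpha_i y_i K(x_i, x) + b with
b = -(max_{y_i=-1} w.x_i + min_{y_i=+1} w.x_i)/2 by default
(``bias="paper"`` reproduces the double-max variant printed in some
descriptions, which coincides only when the positive margin is symmetric).
Sign 0 is classified -1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

from .core import LabelVector, PredictionResult
from .kernels import KernelMatrix

C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class SDPSVMModel:
    mu: np.ndarray  # kernel weights (Lagrange multipliers of the QCQP)
    alpha: np.ndarray  # SVM dual variables, 0 <= alpha <= C
    b: float
    C: float
    c_trace: float
    y_train: np.ndarray
    traces: np.ndarray  # r_i = trace(K_i)
    t: float  # epigraph variable at the optimum
    objective: float  # 2 a^T e - c t at the optimum

    @property
    def support_ids(self) -> np.ndarray:
        return np.flatnonzero(self.alpha > 1e-8)

    @property
    def mu_normalized(self) -> np.ndarray:
        s = self.mu.sum()
        return self.mu / s if s > 0 else self.mu


def _as_K(K) -> np.ndarray:
    return K.K if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)


def sdp_svm_fit(
    Ks: Sequence,
    y_train,
    C: float = 1.0,
    c_trace: float | None = None,
    bias: Literal["standard", "paper"] = "standard",
    jitter: float = 1e-8,
    gtol: float = 1e-10,
    max_iter: int = 2000,
) -> SDPSVMModel:
    """Solve the multiple-kernel QCQP and recover (alpha, mu, b)."""
    yv = y_train.labels if isinstance(y_train, LabelVector) else np.asarray(y_train)
    yv = yv.astype(float)
    if C <= 0:
        raise ValueError("box constraint C must be positive")
    Kmats = [_as_K(K) for K in Ks]
    n = len(yv)
    if not ((yv == 1).any() and (yv == -1).any()):
        raise ValueError("training labels must contain both classes")
    Kmats = [K + jitter * np.eye(n) for K in Kmats]
    r = np.array([np.trace(K) for K in Kmats])
    if (r <= 0).any():
        raise ValueError("every kernel needs a positive trace")
    c = float(c_trace) if c_trace is not None else float(n)
    G = [np.outer(yv, yv) * K for K in Kmats]  # diag(y) K diag(y)
    m = len(G)

    # variables z = (alpha_1..alpha_n, t); minimise c t - 2 sum(alpha)
    grad_lin = np.concatenate([-2.0 * np.ones(n), [c]])

    def fun(z):
        return float(grad_lin @ z)

    def jac(z):
        return grad_lin

    def quad(z):
        a = z[:n]
        return np.array([a @ Gi @ a - r[i] * z[n] for i, Gi in enumerate(G)])

    def quad_jac(z):
        a = z[:n]
        J = np.zeros((m, n + 1))
        for i, Gi in enumerate(G):
            J[i, :n] = 2.0 * (Gi @ a)
            J[i, n] = -r[i]
        return J

    def quad_hess(z, v):
        H = np.zeros((n + 1, n + 1))
        for vi, Gi in zip(v, G):
            H[:n, :n] += 2.0 * vi * Gi
        return H

    n_pos = int((yv == 1).sum())
    n_neg = n - n_pos
    eps = min(C, 1.0) * 1e-3
    a0 = np.where(yv == 1, eps / n_pos, eps / n_neg)
    t0 = max(float(a0 @ Gi @ a0 / ri) for Gi, ri in zip(G, r)) + 1e-6
    z0 = np.concatenate([a0, [t0]])

    Aeq = np.concatenate([yv, [0.0]])
    constraints = [
        optimize.LinearConstraint(Aeq[None, :], 0.0, 0.0),
        optimize.NonlinearConstraint(quad, -np.inf, 0.0, jac=quad_jac, hess=quad_hess),
    ]
    bounds = optimize.Bounds(
        np.concatenate([np.zeros(n), [0.0]]),
        np.concatenate([np.full(n, C), [np.inf]]),
    )
    res = optimize.minimize(
        fun,
        z0,
        jac=jac,
        hess=lambda z: np.zeros((n + 1, n + 1)),
        method="trust-constr",
        bounds=bounds,
        constraints=constraints,
        options={"gtol": gtol, "xtol": 1e-12, "maxiter": max_iter},
    )
    if res.status == 0 or not np.all(np.isfinite(res.x)):
        raise RuntimeError(f"QCQP solver failed: {res.message}")
    alpha = np.clip(res.x[:n], 0.0, C)
    t = float(res.x[n])
    # mu_i = multiplier of quadratic constraint i (KKT identification)
    mu = np.asarray(res.v[1], dtype=float).ravel()
    mu = np.clip(mu, 0.0, None)
    scale = mu @ r
    if scale > 0:
        mu *= c / scale  # enforce trace(sum mu_i K_i) = c exactly
    else:  # all constraints inactive (alpha = 0 degenerate case)
        mu = c / (m * r)  # uniform trace contribution per kernel
    model = SDPSVMModel(
        mu=mu,
        alpha=alpha,
        b=0.0,
        C=C,
        c_trace=c,
        y_train=yv.astype(int),
        traces=r,
        t=t,
        objective=float(2.0 * alpha.sum() - c * t),
    )
    Kbar = combined_kernel(model, Kmats)
    w_dot = Kbar @ (alpha * yv)  # w.x_i over training samples, no bias
    neg_term = w_dot[yv == -1].max()
    pos_term = w_dot[yv == 1].max() if bias == "paper" else w_dot[yv == 1].min()
    model.b = -(neg_term + pos_term) / 2.0
    return model


def combined_kernel(model: SDPSVMModel, Kmats: Sequence) -> np.ndarray:
    """sum_i mu_i K_i over whatever blocks are supplied."""
    out = np.zeros_like(_as_K(Kmats[0]))
    for mu_i, K in zip(model.mu, Kmats):
        out += mu_i * _as_K(K)
    return out


def decision_values(model: SDPSVMModel, K_test_blocks: Sequence) -> np.ndarray:
    """f(x) = sum_i alpha_i y_i K(x_i, x) + b for test-vs-train blocks."""
    blocks = [_as_K(K) for K in K_test_blocks]
    n_train = len(model.alpha)
    for B in blocks:
        if B.shape[1] != n_train:
            raise ValueError(
                f"test-vs-train block has {B.shape[1]} columns, expected {n_train}"
            )
    Kbar = combined_kernel(model, blocks)
    return Kbar @ (model.alpha * model.y_train) + model.b


def sdp_svm_predict(
    model: SDPSVMModel, K_test_blocks: Sequence, sample_ids=None
) -> PredictionResult:
    """Classify sign(f); f = 0 goes to -1."""
    f = decision_values(model, K_test_blocks)
    return PredictionResult(np.where(f > 0, 1, -1), f, "decision_value", sample_ids)


def tune_C(
    Ks: Sequence,
    y_train,
    grid=C_GRID,
    k: int = 5,
    seed: int = 0,
) -> float:
    """Stratified k-fold CV over the C grid; ties toward smaller C."""
    from sklearn.model_selection import StratifiedKFold

    yv = y_train.labels if isinstance(y_train, LabelVector) else np.asarray(y_train)
    Kmats = [_as_K(K) for K in Ks]
    grid = sorted(grid)
    if len(grid) == 1:
        return float(grid[0])
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    acc = np.zeros(len(grid))
    for tr, te in cv.split(yv, yv):
        K_tr = [K[np.ix_(tr, tr)] for K in Kmats]
        K_cross = [K[np.ix_(te, tr)] for K in Kmats]
        for gi, Cval in enumerate(grid):
            model = sdp_svm_fit(K_tr, yv[tr], C=Cval)
            pred = sdp_svm_predict(model, K_cross)
            acc[gi] += np.mean(pred.predicted_labels == yv[te])
    return float(grid[int(np.argmax(np.round(acc, 12)))])
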