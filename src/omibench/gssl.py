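"""Graph-based semi-supervised learning (label propagation on Laplacians).

Single network: scores f minimise ||f - y||^2 + c f^T L f, i.e. solve
(I + cL) f = y, where unlabelled nodes carry y_i = 0. Multiple networks:
the smoothness constraint f^T L_k f <= gamma over every network leads, via
Lagrange duality, to

    min_alpha  y^T (I + sum_k alpha_k L_k)^{-1} y
    s.t.       alpha_k >= 0,  sum_k alpha_k <= c,

with f = (I + sum_k alpha_k L_k)^{-1} y at the optimum. alpha_k acts as the
learned weight of network k; networks with alpha_k = 0 are redundant.
Unlabelled nodes are classified by the median cut-off: assign +1 iff f_i is
strictly closer to the median score of the +1-labelled nodes than to that of
the -1-labelled nodes (ties go to -1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from .core import LabelVector, PredictionResult
from .graphs import LaplacianMatrix

C_GRID = (0.001, 0.005, 0.01, 0.05, 0.1, 0.25, 0.5, 1, 1.5, 5, 10, 25, 50, 100)


@dataclass
class GraphSSLModel:
    f: np.ndarray
    c: float
    alphas: np.ndarray | None = None  # per-network weights (multi-network case)
    networks: list[LaplacianMatrix] | None = None


def _as_L(L) -> np.ndarray:
    return L.L if isinstance(L, LaplacianMatrix) else np.asarray(L, dtype=float)


def _as_y(y, n: int) -> np.ndarray:
    if isinstance(y, LabelVector):
        vec = y.labels.astype(float)
    else:
        vec = np.asarray(y, dtype=float)
    if len(vec) != n:
        raise ValueError("label vector length does not match graph size")
    return vec


def solve_single(L, y, c: float) -> GraphSSLModel:
    """Solve (I + cL) f = y by a dense symmetric linear solve."""
    if c < 0:
        raise ValueError("trade-off parameter c must be non-negative")
    Lm = _as_L(L)
    yv = _as_y(y, Lm.shape[0])
    A = np.eye(Lm.shape[0]) + c * Lm
    f = linalg.solve(A, yv, assume_a="sym" if np.allclose(Lm, Lm.T) else "gen")
    return GraphSSLModel(f=f, c=c, networks=[L] if isinstance(L, LaplacianMatrix) else None)


def median_cutoff_classify(
    f: np.ndarray, y_train: LabelVector | np.ndarray, sample_ids=None
) -> PredictionResult:
    """Median cut-off rule on function scores (tie -> -1)."""
    f = np.asarray(f, dtype=float)
    yv = y_train.labels if isinstance(y_train, LabelVector) else np.asarray(y_train)
    if not ((yv == 1).any() and (yv == -1).any()):
        raise ValueError("median cut-off needs labelled nodes of both classes")
    m_pos = np.median(f[yv == 1])
    m_neg = np.median(f[yv == -1])
    labels = np.where(np.abs(f - m_pos) < np.abs(f - m_neg), 1, -1)
    return PredictionResult(labels, f, "function_score", sample_ids)


def _objective_and_grad(alpha: np.ndarray, Ls: list[np.ndarray], yv: np.ndarray):
    """y^T (I + sum a_k L_k)^{-1} y and its gradient -u^T L_k u, u = A^{-1}y."""
    n = Ls[0].shape[0]
    A = np.eye(n)
    for a, Lk in zip(alpha, Ls):
        A += a * Lk
    # plain LU: symmetrised sharpened Laplacians need not be PSD, and the
    # indefinite solver's forward error is larger on ill-conditioned systems
    u = linalg.solve(A, yv)
    obj = float(yv @ u)
    grad = np.array([-(u @ Lk @ u) for Lk in Ls])
    return obj, grad, u


def solve_multi(
    Ls: list,
    y,
    c: float,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> GraphSSLModel:
    """Optimise network weights alpha on the simplex {a >= 0, sum a <= c}.

    Solved by SLSQP with the analytic gradient
    d/da_k = -y^T A^{-1} L_k A^{-1} y, A = I + sum a_k L_k, starting from the
    uniform feasible point c/m. The symmetrised Laplacians must be PSD for
    the objective to be convex.
    """
    if c <= 0:
        raise ValueError("c must be positive for multi-network integration")
    Lmats = [_as_L(L) for L in Ls]
    # the objective only sees the symmetric part of each Laplacian
    Lsym = [(L + L.T) / 2.0 for L in Lmats]
    m = len(Lsym)
    n = Lsym[0].shape[0]
    yv = _as_y(y, n)

    def fun(a):
        obj, grad, _ = _objective_and_grad(a, Lsym, yv)
        return obj, grad

    # The dual objective is only well-posed while A = I + sum a_k L_k stays
    # positive definite. Symmetric Laplacians are PSD so any a >= 0 is fine;
    # symmetrised *sharpened* Laplacians can be indefinite, in which case the
    # objective is unbounded beyond the singularity of A. Restrict the
    # weights so A keeps a definite margin: sum a_k * neg_k <= 1 - margin,
    # with neg_k the most negative eigenvalue magnitude of L_k.
    neg = np.array([max(0.0, -float(np.linalg.eigvalsh(Lk).min())) for Lk in Lsym])
    neg[neg < 1e-12] = 0.0
    pd_bound = 1.0 - 1e-2
    constrained = bool((neg > 0).any())

    def project(a):
        """Feasible map onto {a >= 0, sum a <= c, neg.a <= pd_bound}."""
        a = np.clip(a, 0.0, None)
        if a.sum() > c:
            # Euclidean projection onto the simplex {a >= 0, sum a = c}
            u = np.sort(a)[::-1]
            css = np.cumsum(u) - c
            rho = np.nonzero(u - css / (np.arange(m) + 1) > 0)[0][-1]
            a = np.clip(a - css[rho] / (rho + 1.0), 0.0, None)
        if constrained and neg @ a > pd_bound:
            a = a * (pd_bound / (neg @ a))
        return a

    sl_constraints = [
        {"type": "ineq", "fun": lambda a: c - a.sum(), "jac": lambda a: -np.ones(m)}
    ]
    if constrained:
        sl_constraints.append(
            {"type": "ineq", "fun": lambda a: pd_bound - neg @ a, "jac": lambda a: -neg}
        )
    candidates = []
    res = optimize.minimize(
        fun,
        project(np.full(m, c / m)),
        jac=True,
        method="SLSQP",
        bounds=[(0.0, c)] * m,
        constraints=sl_constraints,
        options={"maxiter": max_iter, "ftol": tol},
    )
    candidates.append(project(res.x))
    if not res.success and res.status != 8:  # 8 = positive directional derivative, benign
        # SLSQP can stall on flat objectives; restart from the vertices
        for k in range(m):
            vertex = np.zeros(m)
            vertex[k] = c
            r = optimize.minimize(
                fun, project(vertex), jac=True, method="SLSQP",
                bounds=[(0.0, c)] * m,
                constraints=sl_constraints,
                options={"maxiter": max_iter, "ftol": tol},
            )
            candidates.append(project(r.x))
    best = min(candidates, key=lambda a: _objective_and_grad(a, Lsym, yv)[0])
    # projected-gradient polish: convex objective, guaranteed not to worsen
    alpha = best
    obj, grad, _ = _objective_and_grad(alpha, Lsym, yv)
    step = c
    for _ in range(200):
        trial = project(alpha - step * grad)
        if np.abs(trial - alpha).max() < 1e-14:
            break
        t_obj, t_grad, _ = _objective_and_grad(trial, Lsym, yv)
        if t_obj < obj - 1e-15:
            alpha, obj, grad = trial, t_obj, t_grad
        else:
            step /= 2.0
            if step < 1e-12 * c:
                break
    if not np.all(np.isfinite(alpha)):
        raise RuntimeError(
            f"multi-network weight optimisation diverged (best iterate alpha={best})"
        )
    _, _, f = _objective_and_grad(alpha, Lsym, yv)
    return GraphSSLModel(f=f, c=c, alphas=alpha, networks=list(Ls))


def multi_objective(alpha, Ls, y) -> float:
    """Public handle on the multi-network objective (used for validation)."""
    Lmats = [(_as_L(L) + _as_L(L).T) / 2.0 for L in Ls]
    yv = _as_y(y, Lmats[0].shape[0])
    obj, _, _ = _objective_and_grad(np.asarray(alpha, dtype=float), Lmats, yv)
    return obj


def tune_c(
    Ls: list,
    y_train: LabelVector,
    grid=C_GRID,
    k: int = 5,
    repeats: int = 5,
    seed: int = 0,
    solver=None,
) -> float:
    """Pick c from the grid by repeated stratified k-fold CV accuracy.

    Each fold's labels are masked to 0, scores are propagated from the
    remaining labelled nodes over the full (transductive) graph restricted
    to the training samples, and the fold is classified by the median
    cut-off. Ties break toward smaller c.
    """
    from sklearn.model_selection import RepeatedStratifiedKFold

    grid = sorted(grid)
    if len(grid) == 1:
        return float(grid[0])
    yv = y_train.labels if isinstance(y_train, LabelVector) else np.asarray(y_train)
    lab_idx = np.flatnonzero(yv != 0)
    solve = solver or (lambda Ls_, ym, c: solve_multi(Ls_, ym, c) if len(Ls_) > 1 else solve_single(Ls_[0], ym, c))
    cv = RepeatedStratifiedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
    acc = np.zeros(len(grid))
    for tr, te in cv.split(lab_idx, yv[lab_idx]):
        hide = lab_idx[te]
        ym = yv.copy().astype(float)
        ym[hide] = 0.0
        for gi, c in enumerate(grid):
            model = solve(Ls, ym, c)
            pred = median_cutoff_classify(model.f, ym)
            acc[gi] += np.mean(pred.predicted_labels[hide] == yv[hide])
    best = int(np.argmax(np.round(acc, 12)))  # argmax takes the first (smallest c) on ties
    return float(grid[best])
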