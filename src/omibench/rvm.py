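"""Relevance vector machine classification and its AdaBoost ensemble.

The RVM is a sparse Bayesian kernel classifier: the latent score is
Y(x; w) = sum_i w_i k(x, x_i) over training samples, mapped to
P(y = 1) = sigmoid(Y). Each weight carries an independent Gaussian prior
with its own precision a_i; precisions are re-estimated by type-II maximum
likelihood with a Laplace approximation to the logistic likelihood
(iterated reweighted least squares for the posterior mode, then the
standard gamma_i = 1 - a_i * Sigma_ii update). Weights whose precision
diverges are pruned; the surviving training samples are the relevance
vectors.

Several sources are integrated by fitting one RVM (or boosted ensemble)
per source kernel and averaging the predicted probabilities; the averaged
probability is thresholded at 0.5 (p = 0.5 classifies -1).

AdaBoost-RVM trains each round's RVM on a weighted subsample (drawn
without replacement, selection probability proportional to the current
sample weights), measures the weighted error eps_t over the FULL training
set, skips rounds with eps_t >= 0.5, stores learner weight
alpha_t = ln((1 - eps_t)/eps_t)/2, and reweights samples by e^{+-alpha_t}
with renormalisation to sum 1. The ensemble score is
sum_t alpha_t h_t(x) with h_t the round's +-1 prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .core import LabelVector, PredictionResult

RESAMPLE_GRID = (0.2, 0.4, 0.6, 0.8)
ITERATION_GRID = (1, 5, 10, 20, 30)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class RVMModel:
    relevance_ids: np.ndarray  # indices into the training set
    weights: np.ndarray  # coefficients over the relevance vectors
    iterations: int
    converged: bool

    def scores(self, K_test_block: np.ndarray) -> np.ndarray:
        """Latent Y(x) for test rows of a test-vs-train kernel block."""
        K = np.asarray(K_test_block, dtype=float)
        return K[:, self.relevance_ids] @ self.weights


def rvm_fit(
    K_train,
    y_train,
    max_iter: int = 500,
    tol: float = 1e-3,
    prune_threshold: float = 1e9,
    init_alpha: float = 1.0,
) -> RVMModel:
    """Type-II ML sparse Bayesian logistic fit on a precomputed kernel."""
    from .kernels import KernelMatrix

    K = K_train.K if isinstance(K_train, KernelMatrix) else np.asarray(K_train, dtype=float)
    yv = y_train.labels if isinstance(y_train, LabelVector) else np.asarray(y_train)
    if not ((yv == 1).any() and (yv == -1).any()):
        raise ValueError("RVM training needs both classes")
    t = (yv + 1) / 2.0  # {0, 1} targets
    n = K.shape[0]
    active = np.arange(n)
    a = np.full(n, init_alpha)
    w = np.zeros(n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Phi = K[:, active]
        wa = w[: len(active)]
        # Laplace: Newton/IRLS for the posterior mode
        for _ in range(50):
            z = Phi @ wa
            p = _sigmoid(z)
            g = Phi.T @ (t - p) - a[active] * wa
            Bdiag = np.clip(p * (1 - p), 1e-10, None)
            H = (Phi.T * Bdiag) @ Phi + np.diag(a[active])
            try:
                step = linalg.solve(H, g, assume_a="pos")
            except linalg.LinAlgError:
                step = linalg.lstsq(H, g)[0]
            wa_new = wa + step
            if np.max(np.abs(step)) < 1e-8:
                wa = wa_new
                break
            wa = wa_new
        z = Phi @ wa
        p = _sigmoid(z)
        Bdiag = np.clip(p * (1 - p), 1e-10, None)
        H = (Phi.T * Bdiag) @ Phi + np.diag(a[active])
        try:
            Sigma = linalg.inv(H)
        except linalg.LinAlgError:
            Sigma = np.linalg.pinv(H)
        gamma = 1.0 - a[active] * np.diag(Sigma)
        a_new = np.where(wa**2 > 0, np.clip(gamma, 1e-12, None) / np.clip(wa**2, 1e-300, None), prune_threshold * 10)
        delta = np.max(np.abs(np.log(np.clip(a_new, 1e-300, None)) - np.log(np.clip(a[active], 1e-300, None))))
        a[active] = a_new
        keep = a[active] < prune_threshold
        if keep.sum() == 0:  # everything pruned: keep the best single vector
            keep[np.argmin(a[active])] = True
        active = active[keep]
        wa = wa[keep]
        w = np.zeros(n)
        w[: len(active)] = wa
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("RVM hyperparameter loop hit max_iter without converging", stacklevel=2)
    return RVMModel(relevance_ids=active, weights=wa, iterations=it, converged=converged)


def rvm_predict_proba(model: RVMModel, K_test_block: np.ndarray) -> np.ndarray:
    """P(y = 1 | x) = sigmoid(Y(x)); strictly inside (0, 1)."""
    return _sigmoid(model.scores(K_test_block))


def integrate_probabilities(
    Ps: list[np.ndarray], sample_ids=None
) -> PredictionResult:
    """Average per-source probabilities; p > 0.5 -> +1 (p = 0.5 -> -1)."""
    arrs = [np.asarray(p, dtype=float) for p in Ps]
    lengths = {len(p) for p in arrs}
    if len(lengths) != 1:
        raise ValueError("probability vectors must all have the same length")
    pbar = np.mean(arrs, axis=0)
    return PredictionResult(np.where(pbar > 0.5, 1, -1), pbar, "probability", sample_ids)


# ---------------------------------------------------------------------------
# AdaBoost


@dataclass
class BoostedRVM:
    learners: list[tuple[float, RVMModel]]  # (alpha_t, learner)
    resample_fraction: float
    max_iterations: int
    skipped_iterations: int = 0
    fallback_used: bool = False
    weight_history: list[np.ndarray] = field(default_factory=list)

    def scores(self, K_test_block: np.ndarray) -> np.ndarray:
        """Ensemble score sum_t alpha_t h_t(x), h_t in {-1, +1}."""
        K = np.asarray(K_test_block, dtype=float)
        out = np.zeros(K.shape[0])
        for alpha_t, learner in self.learners:
            h = np.where(learner.scores(K) > 0, 1.0, -1.0)
            out += alpha_t * h
        return out

    def predict_proba(self, K_test_block: np.ndarray) -> np.ndarray:
        return _sigmoid(self.scores(K_test_block))


def adaboost_rvm_fit(
    K_train,
    y_train,
    resample_fraction: float = 0.4,
    max_iter: int = 10,
    seed: int = 0,
    rvm_kwargs: dict | None = None,
) -> BoostedRVM:
    """Boost RVM learners on weighted subsamples of the training set."""
    from .kernels import KernelMatrix

    K = K_train.K if isinstance(K_train, KernelMatrix) else np.asarray(K_train, dtype=float)
    yv = y_train.labels if isinstance(y_train, LabelVector) else np.asarray(y_train)
    if not 0.0 < resample_fraction <= 1.0:
        raise ValueError("resample_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    N = len(yv)
    n_sub = max(4, int(round(resample_fraction * N)))
    n_sub = min(n_sub, N)
    w = np.full(N, 1.0 / N)
    ens = BoostedRVM([], resample_fraction, max_iter)
    kwargs = rvm_kwargs or {}
    for _ in range(max_iter):
        for _attempt in range(10):
            sub = rng.choice(N, size=n_sub, replace=False, p=w)
            if (yv[sub] == 1).any() and (yv[sub] == -1).any():
                break
        else:
            ens.skipped_iterations += 1
            continue
        learner = rvm_fit(K[np.ix_(sub, sub)], yv[sub], **kwargs)
        # re-key relevance indices to the full training set
        learner = RVMModel(sub[learner.relevance_ids], learner.weights,
                           learner.iterations, learner.converged)
        h = np.where(learner.scores(K) > 0, 1, -1)
        miss = h != yv
        eps = float(w[miss].sum())
        if eps >= 0.5:
            ens.skipped_iterations += 1
            continue
        eps = max(eps, 1e-10)  # eps = 0: cap the learner weight
        alpha_t = 0.5 * np.log((1.0 - eps) / eps)
        ens.learners.append((alpha_t, learner))
        w = np.where(miss, w * np.exp(alpha_t), w * np.exp(-alpha_t))
        w /= w.sum()
        ens.weight_history.append(w.copy())
    if not ens.learners:
        warnings.warn(
            "every boosting round was skipped (eps_t >= 0.5); "
            "falling back to a single RVM on the full training set",
            stacklevel=2,
        )
        learner = rvm_fit(K, yv, **kwargs)
        ens.learners.append((1.0, learner))
        ens.fallback_used = True
    return ens


def tune_boost(
    K_train,
    y_train,
    resample_grid=RESAMPLE_GRID,
    iteration_grid=ITERATION_GRID,
    k: int = 5,
    seed: int = 0,
    rvm_kwargs: dict | None = None,
) -> tuple[float, int]:
    """5-fold CV over the (resample fraction, iteration) grid.

    Ties break toward the smaller iteration count, then the smaller
    fraction (the cheaper model).
    """
    from sklearn.model_selection import StratifiedKFold
    from .kernels import KernelMatrix

    K = K_train.K if isinstance(K_train, KernelMatrix) else np.asarray(K_train, dtype=float)
    yv = y_train.labels if isinstance(y_train, LabelVector) else np.asarray(y_train)
    pairs = [(f, it) for it in sorted(iteration_grid) for f in sorted(resample_grid)]
    if len(pairs) == 1:
        return pairs[0]
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    acc = np.zeros(len(pairs))
    for fold, (tr, te) in enumerate(cv.split(yv, yv)):
        K_tr = K[np.ix_(tr, tr)]
        K_cross = K[np.ix_(te, tr)]
        for gi, (frac, iters) in enumerate(pairs):
            ens = adaboost_rvm_fit(
                K_tr, yv[tr], resample_fraction=frac, max_iter=iters,
                seed=seed * 1000 + fold, rvm_kwargs=rvm_kwargs,
            )
            pred = np.where(ens.scores(K_cross) > 0, 1, -1)
            acc[gi] += np.mean(pred == yv[te])
    best = int(np.argmax(np.round(acc, 12)))
    frac, iters = pairs[best]
    return float(frac), int(iters)
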