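"""Uniform fit/predict adapters for the seven integration algorithms.

Every adapter is a callable

    fit_predict(study, train_idx, test_idx, seed) -> PredictionResult

over the test samples, where ``study`` arrives with the test labels already
masked to 0. The graph-based methods are transductive: test samples sit in
the sample-similarity graph as unlabelled nodes and receive propagated
scores. The kernel-based methods are inductive: models are fitted on the
training block of each kernel and applied to the test-vs-train block.
Feature standardisation always uses training-sample statistics.

Hyperparameter policy: each adapter takes either a fixed value or "auto"
(cross-validated on the training samples with the method's grid). The
defaults fix cheap, mid-grid values so that large benchmark runs stay
tractable; see docs/methods.md.
"""

from __future__ import annotations

import numpy as np

from . import bayesnet, composite, gssl, kernels, rvm, sdpsvm, sharpening
from .core import FeatureMatrix, MultiOmicsStudy, PredictionResult, feature_stats, zscore_features
from .graphs import WeightMatrix, correlation_weights, laplacian


def _zscored_sources(study: MultiOmicsStudy, train_idx) -> list[FeatureMatrix]:
    out = []
    for src in study.sources:
        out.append(zscore_features(src, stats=feature_stats(src, train_idx)))
    return out


def _subset_pred(pred: PredictionResult, test_idx, sample_ids) -> PredictionResult:
    test_idx = np.asarray(test_idx, dtype=int)
    return PredictionResult(
        pred.predicted_labels[test_idx],
        pred.scores[test_idx],
        pred.score_kind,
        [sample_ids[i] for i in test_idx],
    )


def _resolve_c(c, Ls, y_masked, seed):
    if c != "auto":
        return float(c)
    return gssl.tune_c(Ls, y_masked, seed=seed)


class GraphSSLIntegrator:
    """Multi-network label propagation with convex network weighting."""

    def __init__(self, c: float | str = 1.0, method: str = "pearson"):
        self.c = c
        self.method = method

    def _weights(self, study, train_idx) -> list[WeightMatrix]:
        return [correlation_weights(Z, self.method) for Z in _zscored_sources(study, train_idx)]

    def __call__(self, study, train_idx, test_idx, seed=0) -> PredictionResult:
        Ws = self._weights(study, train_idx)
        y = study.labels
        train_idx = np.asarray(train_idx, dtype=int)
        if self.c == "auto":
            sub_Ls = [laplacian(W.restrict(train_idx)) for W in Ws]
            c = gssl.tune_c(sub_Ls, y.labels[train_idx], seed=seed)
        else:
            c = float(self.c)
        Ls = [laplacian(W) for W in Ws]
        model = (
            gssl.solve_multi(Ls, y.labels.astype(float), c)
            if len(Ls) > 1
            else gssl.solve_single(Ls[0], y.labels.astype(float), c)
        )
        pred = gssl.median_cutoff_classify(model.f, y.labels)
        return _subset_pred(pred, test_idx, study.sample_ids)


class GraphSharpeningIntegrator(GraphSSLIntegrator):
    """Label propagation on sharpened (directed) graphs."""

    def __call__(self, study, train_idx, test_idx, seed=0) -> PredictionResult:
        Ws = self._weights(study, train_idx)
        y = study.labels
        train_idx = np.asarray(train_idx, dtype=int)
        sharp = [sharpening.sharpen(W, y) for W in Ws]
        Ls = [sharpening.sharpened_laplacian(g) for g in sharp]
        if self.c == "auto":
            # tune on the training subgraph, resharpened per fold by the solver
            sub_Ws = [W.restrict(train_idx) for W in Ws]
            y_tr = y.labels[train_idx]

            def solver(_Ls, ym, c):
                Lk = [
                    sharpening.sharpened_laplacian(sharpening.sharpen(W, np.asarray(ym, dtype=int)))
                    for W in sub_Ws
                ]
                return sharpening.solve_sharpened(Lk, ym, c)

            c = gssl.tune_c([laplacian(W) for W in sub_Ws], y_tr, seed=seed, solver=solver)
        else:
            c = float(self.c)
        model = sharpening.solve_sharpened(Ls, y.labels.astype(float), c)
        pred = gssl.median_cutoff_classify(model.f, y.labels)
        return _subset_pred(pred, test_idx, study.sample_ids)


class CompositeNetworkIntegrator:
    """Regression-weighted composite association network (c fixed at 1)."""

    def __init__(self, convention: str = "printed", method: str = "pearson"):
        self.convention = convention
        self.method = method
        self.last_weights = None  # diagnostics from the most recent call

    def __call__(self, study, train_idx, test_idx, seed=0) -> PredictionResult:
        Ws = [
            correlation_weights(Z, self.method)
            for Z in _zscored_sources(study, train_idx)
        ]
        _, pred, weights = composite.can_fit_predict(
            Ws, study.labels, convention=self.convention
        )
        self.last_weights = weights
        return _subset_pred(pred, test_idx, study.sample_ids)


class BayesNetIntegrator:
    """Posterior-odds classifier over discretised per-source scores."""

    def __init__(self, variant: str = "simple", n_bins: int = 4,
                 pseudocount: float = 1.0, edge_threshold: float = 0.3):
        self.variant = variant
        self.n_bins = n_bins
        self.pseudocount = pseudocount
        self.edge_threshold = edge_threshold

    def __call__(self, study, train_idx, test_idx, seed=0) -> PredictionResult:
        train_idx = np.asarray(train_idx, dtype=int)
        test_idx = np.asarray(test_idx, dtype=int)
        train_mats = [src.values[train_idx] for src in study.sources]
        model = bayesnet.fit_bayes_net(
            train_mats,
            study.labels.labels[train_idx],
            variant=self.variant,
            n_bins=self.n_bins,
            pseudocount=self.pseudocount,
            edge_threshold=self.edge_threshold,
        )
        binned = model.transform([src.values[test_idx] for src in study.sources])
        return bayesnet.posterior_odds_classify(
            model, binned, [study.sample_ids[i] for i in test_idx]
        )


class _KernelMixin:
    def __init__(self, kernel: str = "rbf", sigma="median"):
        self.kernel = kernel
        self.sigma = sigma

    def _blocks(self, study, train_idx, test_idx, seed):
        """(K_train, K_cross) per source, sigma resolved per source."""
        train_idx = np.asarray(train_idx, dtype=int)
        test_idx = np.asarray(test_idx, dtype=int)
        y_tr = study.labels.labels[train_idx]
        K_trains, K_crosses = [], []
        for Z in _zscored_sources(study, train_idx):
            V_tr, V_te = Z.values[train_idx], Z.values[test_idx]
            if self.kernel == "linear":
                K_trains.append(kernels.linear_kernel(V_tr).K)
                K_crosses.append(kernels.linear_cross(V_tr, V_te))
                continue
            if self.sigma == "median":
                sig = kernels.median_heuristic_grid(V_tr, powers=(0,))[0]
            elif self.sigma == "auto":
                sig = kernels.tune_sigma(V_tr, y_tr, seed=seed)
            else:
                sig = float(self.sigma)
            K_trains.append(kernels.rbf_kernel(V_tr, sig).K)
            K_crosses.append(kernels.rbf_cross(V_tr, V_te, sig))
        return K_trains, K_crosses, y_tr


class SDPSVMIntegrator(_KernelMixin):
    """Multiple-kernel-learning SVM (QCQP dual)."""

    def __init__(self, C=1.0, kernel: str = "rbf", sigma="median",
                 bias: str = "standard"):
        super().__init__(kernel, sigma)
        self.C = C
        self.bias = bias
        self.last_model = None

    def __call__(self, study, train_idx, test_idx, seed=0) -> PredictionResult:
        K_trains, K_crosses, y_tr = self._blocks(study, train_idx, test_idx, seed)
        C = sdpsvm.tune_C(K_trains, y_tr, seed=seed) if self.C == "auto" else float(self.C)
        model = sdpsvm.sdp_svm_fit(K_trains, y_tr, C=C, bias=self.bias)
        self.last_model = model
        test_idx = np.asarray(test_idx, dtype=int)
        return sdpsvm.sdp_svm_predict(
            model, K_crosses, [study.sample_ids[i] for i in test_idx]
        )


class RVMIntegrator(_KernelMixin):
    """One RVM per source; probabilities averaged, cut at 0.5."""

    def __call__(self, study, train_idx, test_idx, seed=0) -> PredictionResult:
        K_trains, K_crosses, y_tr = self._blocks(study, train_idx, test_idx, seed)
        probs = []
        for K_tr, K_cross in zip(K_trains, K_crosses):
            model = rvm.rvm_fit(K_tr, y_tr)
            probs.append(rvm.rvm_predict_proba(model, K_cross))
        test_idx = np.asarray(test_idx, dtype=int)
        return rvm.integrate_probabilities(
            probs, [study.sample_ids[i] for i in test_idx]
        )


class AdaBoostRVMIntegrator(_KernelMixin):
    """One boosted-RVM ensemble per source; probabilities averaged."""

    def __init__(self, resample=0.4, iterations=10, kernel: str = "rbf",
                 sigma="median"):
        super().__init__(kernel, sigma)
        self.resample = resample
        self.iterations = iterations

    def __call__(self, study, train_idx, test_idx, seed=0) -> PredictionResult:
        K_trains, K_crosses, y_tr = self._blocks(study, train_idx, test_idx, seed)
        probs = []
        for k, (K_tr, K_cross) in enumerate(zip(K_trains, K_crosses)):
            if self.resample == "auto" or self.iterations == "auto":
                frac, iters = rvm.tune_boost(K_tr, y_tr, seed=seed)
            else:
                frac, iters = float(self.resample), int(self.iterations)
            ens = rvm.adaboost_rvm_fit(
                K_tr, y_tr, resample_fraction=frac, max_iter=iters, seed=seed + k
            )
            probs.append(ens.predict_proba(K_cross))
        test_idx = np.asarray(test_idx, dtype=int)
        return rvm.integrate_probabilities(
            probs, [study.sample_ids[i] for i in test_idx]
        )


ALGORITHM_NAMES = (
    "graph_ssl",
    "graph_sharpening",
    "composite_network",
    "bayes_net",
    "sdp_svm",
    "rvm",
    "adaboost_rvm",
)


def make_algorithms(names=ALGORITHM_NAMES, **overrides) -> dict:
    """Build the benchmark's algorithm dictionary with default settings.

    ``overrides`` maps an algorithm name to a kwargs dict for its adapter.
    """
    factories = {
        "graph_ssl": GraphSSLIntegrator,
        "graph_sharpening": GraphSharpeningIntegrator,
        "composite_network": CompositeNetworkIntegrator,
        "bayes_net": BayesNetIntegrator,
        "sdp_svm": SDPSVMIntegrator,
        "rvm": RVMIntegrator,
        "adaboost_rvm": AdaBoostRVMIntegrator,
    }
    unknown = set(names) - set(factories)
    if unknown:
        raise ValueError(
            f"unknown algorithm(s) {sorted(unknown)}; valid names: {sorted(factories)}"
        )
    return {name: factories[name](**overrides.get(name, {})) for name in names}
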