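"""Standard synthetic experiments exercising all seven integrators.

The two-source demonstration study is the package's reference condition:
n = 150 samples, balanced classes, one informative source (100 features of
which 20 carry a class-mean shift of Delta = 1.5 sd) and one pure-noise
source of 1000 features. Source dimensionalities follow the regime the
methods are built for — omics sources with hundreds to thousands of
features — where a pure-noise source yields a weak, near-uniform sample
network rather than spuriously strong random edges.
"""

from __future__ import annotations

import numpy as np

from .composite import can_fit_predict
from .core import LabelVector, MultiOmicsStudy, feature_stats, zscore_features
from .evaluate import _stratified_split, repeated_holdout
from .graphs import correlation_weights
from .integrators import make_algorithms
from .kernels import median_heuristic_grid, rbf_kernel
from .sdpsvm import sdp_svm_fit
from .simulate import SimulationSpec, SourceSpec, generate_study


def demo_spec(seed: int, n_samples: int = 150, delta: float = 1.5) -> SimulationSpec:
    """Reference two-source study: informative + pure noise."""
    return SimulationSpec(
        n_samples=n_samples,
        sources=[
            SourceSpec(100, 20, delta, name="informative"),
            SourceSpec(1000, 0, name="noise"),
        ],
        class_balance=0.5,
        seed=seed,
    )


def demo_algorithms() -> dict:
    """The seven integrators at their benchmark settings.

    The composite network uses the attraction target convention (mixed
    pairs negative), the variant under which the regression weights track
    informativeness; see docs/methods.md.
    """
    return make_algorithms(composite_network={"convention": "attraction"})


def source_ranking_experiment(n_runs: int = 50, seed: int = 0) -> dict:
    """How often composite alpha and SDP-SVM mu rank the informative source
    above the pure-noise source, over seeded draws of the demo study."""
    comp_wins = 0
    svm_wins = 0
    for run in range(n_runs):
        study = generate_study(demo_spec(seed * 10_000 + run))
        y = study.labels.labels
        rng = np.random.default_rng(seed * 10_000 + run)
        train, test = _stratified_split(y, 0.75, rng)
        ym = y.copy()
        ym[test] = 0
        Zs = [zscore_features(s, stats=feature_stats(s, train)) for s in study.sources]
        Ws = [correlation_weights(Z) for Z in Zs]
        _, _, weights = can_fit_predict(Ws, LabelVector(ym, study.sample_ids),
                                        convention="attraction")
        comp_wins += int(weights.alpha[0] > weights.alpha[1])
        Ks = []
        for Z in Zs:
            V = Z.values[train]
            sig = median_heuristic_grid(V, powers=(0,))[0]
            Ks.append(rbf_kernel(V, sig).K)
        model = sdp_svm_fit(Ks, y[train], C=1.0)
        svm_wins += int(model.mu_normalized[0] > model.mu_normalized[1])
    return {
        "n_runs": n_runs,
        "composite_alpha_informative_first": comp_wins / n_runs,
        "sdp_mu_informative_first": svm_wins / n_runs,
    }


def holdout_benchmark(
    n_runs: int = 10, seed: int = 0, permute_labels: bool = False
):
    """Repeated 75/25 hold-out of all seven integrators on the demo study.

    With ``permute_labels`` each run draws a fresh independent permutation
    of the labels before splitting — the no-signal control under which every
    AUC hovers around 0.5 (a single shared permutation would leave the runs
    correlated through the fixed label/graph pairing).
    """
    study = generate_study(demo_spec(seed + 1))
    if not permute_labels:
        return repeated_holdout(study, demo_algorithms(), n_runs=n_runs, seed=seed)
    algos = demo_algorithms()
    merged = None
    for run in range(n_runs):
        rng = np.random.default_rng(seed * 1000 + run)
        perm = study.labels.labels.copy()
        rng.shuffle(perm)
        shuffled = study.with_labels(LabelVector(perm, study.sample_ids))
        rep = repeated_holdout(shuffled, algos, n_runs=1, seed=seed * 1000 + run)
        if merged is None:
            merged = rep
        else:
            for algo, metrics in rep.per_run.items():
                for metric, vals in metrics.items():
                    merged.per_run[algo][metric].extend(vals)
            for algo, count in rep.failures.items():
                merged.failures[algo] += count
            merged.n_runs += rep.n_runs
    return merged
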