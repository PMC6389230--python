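"""Performance measures and experimental designs for the benchmark.

Metrics: confusion-table accuracy, F1, sensitivity, specificity; rank-based
AUC (concordant + half of tied pairs over P*N). Designs: repeated
stratified 75/25 hold-out (200 runs by default), leave-cluster-out
cross-validation (whole families move between train and test), and
class-imbalance subsampling. Per-run metrics are summarised by their mean
and a percentile-bootstrap 95% confidence interval over runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import LabelVector, MultiOmicsStudy, PredictionResult

logger = logging.getLogger(__name__)

METRICS = ("accuracy", "f1", "auc")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def P(self) -> int:
        return self.tp + self.fn

    @property
    def N(self) -> int:
        return self.tn + self.fp

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fp + self.tn + self.fn)

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else 0.0

    @property
    def sensitivity(self) -> float:
        return self.tp / self.P if self.P else 0.0

    @property
    def specificity(self) -> float:
        return self.tn / self.N if self.N else 0.0


def confusion_metrics(pred, truth) -> ConfusionCounts:
    """Confusion table of {-1,+1} predictions against {-1,+1} truth."""
    pv = pred.predicted_labels if isinstance(pred, PredictionResult) else np.asarray(pred)
    tv = truth.labels if isinstance(truth, LabelVector) else np.asarray(truth)
    if pv.shape != tv.shape:
        raise ValueError("prediction and truth must have the same length")
    if (tv == 0).any():
        raise ValueError("truth labels must be -1/+1 (no unknowns)")
    return ConfusionCounts(
        tp=int(((pv == 1) & (tv == 1)).sum()),
        fp=int(((pv == 1) & (tv == -1)).sum()),
        fn=int(((pv == -1) & (tv == 1)).sum()),
        tn=int(((pv == -1) & (tv == -1)).sum()),
    )


def auc(scores, truth) -> float:
    """Rank-based AUC: (concordant + 0.5 * tied) / (P * N)."""
    sv = np.asarray(scores, dtype=float)
    tv = truth.labels if isinstance(truth, LabelVector) else np.asarray(truth)
    pos = tv == 1
    neg = tv == -1
    P, N = int(pos.sum()), int(neg.sum())
    if P == 0 or N == 0:
        raise ValueError("AUC is undefined with a single class")
    ranks = stats.rankdata(sv)
    return float((ranks[pos].sum() - P * (P + 1) / 2) / (P * N))


def percentile_bootstrap_ci(
    values, level: float = 0.95, n_boot: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Percentile CI of the mean from bootstrap resamples of the values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot bootstrap an empty value set")
    rng = np.random.default_rng(seed)
    means = rng.choice(v, size=(n_boot, v.size), replace=True).mean(axis=1)
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    return float(np.quantile(means, lo)), float(np.quantile(means, hi))


@dataclass
class EvaluationReport:
    """Per-algorithm mean metrics with bootstrap CIs over runs."""

    per_run: dict[str, dict[str, list[float]]]  # algorithm -> metric -> runs
    n_runs: int
    failures: dict[str, int] = field(default_factory=dict)
    ci_seed: int = 0

    def summary(self) -> dict:
        out = {}
        for algo, metrics in self.per_run.items():
            out[algo] = {}
            for metric, vals in metrics.items():
                if not vals:
                    out[algo][metric] = None
                    continue
                lo, hi = percentile_bootstrap_ci(vals, seed=self.ci_seed)
                out[algo][metric] = {
                    "mean": float(np.mean(vals)),
                    "ci95": [lo, hi],
                    "n_runs": len(vals),
                }
        return out

    def to_frame(self):
        import pandas as pd

        rows = []
        for algo, metrics in self.summary().items():
            for metric, cell in metrics.items():
                if cell is None:
                    continue
                rows.append(
                    {
                        "algorithm": algo,
                        "metric": metric,
                        "mean": cell["mean"],
                        "lcl95": cell["ci95"][0],
                        "ucl95": cell["ci95"][1],
                        "n_runs": cell["n_runs"],
                    }
                )
        return pd.DataFrame(rows)


def _score_run(report: EvaluationReport, algo: str, pred: PredictionResult, y_true):
    counts = confusion_metrics(pred, y_true)
    report.per_run[algo]["accuracy"].append(counts.accuracy)
    report.per_run[algo]["f1"].append(counts.f1)
    report.per_run[algo]["auc"].append(auc(pred.scores, y_true))


def _new_report(algorithms, n_runs, seed) -> EvaluationReport:
    return EvaluationReport(
        per_run={a: {m: [] for m in METRICS} for a in algorithms},
        n_runs=n_runs,
        failures={a: 0 for a in algorithms},
        ci_seed=seed,
    )


def _stratified_split(y: np.ndarray, train_frac: float, rng: np.random.Generator):
    train_idx = []
    for cls in (1, -1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_tr = int(round(train_frac * len(idx)))
        n_tr = min(max(n_tr, 1), len(idx) - 1)
        train_idx.append(idx[:n_tr])
    train = np.sort(np.concatenate(train_idx))
    test = np.setdiff1d(np.arange(len(y)), train)
    return train, test


def repeated_holdout(
    study: MultiOmicsStudy,
    algorithms: dict,
    n_runs: int = 200,
    train_frac: float = 0.75,
    seed: int = 0,
) -> EvaluationReport:
    """Repeated stratified hold-out: 75% train / 25% test, many runs.

    ``algorithms`` maps a name to a callable
    ``fit_predict(study, train_idx, test_idx, seed) -> PredictionResult``
    returning predictions for the test samples only; test labels are hidden
    from it (the study it receives has them set to 0). A failing run is
    logged and excluded for that algorithm.
    """
    y = study.labels.labels
    report = _new_report(algorithms, n_runs, seed)
    rng = np.random.default_rng(seed)
    for run in range(n_runs):
        train, test = _stratified_split(y, train_frac, rng)
        masked = study.with_labels(study.labels.mask(test))
        run_seed = int(rng.integers(0, 2**31 - 1))
        for name, fit_predict in algorithms.items():
            try:
                pred = fit_predict(masked, train, test, run_seed)
                _score_run(report, name, pred, y[test])
            except Exception:  # noqa: BLE001 — a run failure must not kill the benchmark
                logger.exception("run %d failed for %s", run, name)
                report.failures[name] += 1
    return report


def leave_cluster_out(
    study: MultiOmicsStudy,
    algorithms: dict,
    n_train_clusters: int = 12,
    n_runs: int = 200,
    seed: int = 0,
    max_retries: int = 100,
) -> EvaluationReport:
    """Cluster-respecting CV: whole clusters are train or test, never both."""
    if study.clusters is None:
        raise ValueError("leave_cluster_out needs a study with cluster ids")
    y = study.labels.labels
    cluster_ids = np.unique(study.clusters)
    if n_train_clusters >= len(cluster_ids):
        raise ValueError("n_train_clusters must be smaller than the number of clusters")
    report = _new_report(algorithms, n_runs, seed)
    rng = np.random.default_rng(seed)
    for run in range(n_runs):
        for _retry in range(max_retries):
            train_clusters = rng.choice(cluster_ids, size=n_train_clusters, replace=False)
            in_train = np.isin(study.clusters, train_clusters)
            train = np.flatnonzero(in_train)
            test = np.flatnonzero(~in_train)
            ok = (
                (y[test] == 1).any() and (y[test] == -1).any()
                and (y[train] == 1).any() and (y[train] == -1).any()
            )
            if ok:
                break
        else:
            raise RuntimeError(
                f"could not draw a cluster split with both classes in train and test "
                f"after {max_retries} tries"
            )
        masked = study.with_labels(study.labels.mask(test))
        run_seed = int(rng.integers(0, 2**31 - 1))
        for name, fit_predict in algorithms.items():
            try:
                pred = fit_predict(masked, train, test, run_seed)
                _score_run(report, name, pred, y[test])
            except Exception:  # noqa: BLE001
                logger.exception("run %d failed for %s", run, name)
                report.failures[name] += 1
    return report


def imbalance_experiment(
    study: MultiOmicsStudy,
    algorithms: dict,
    ratios=((5, 1), (5, 2)),
    n_runs: int = 200,
    train_frac: float = 0.75,
    seed: int = 0,
) -> dict[str, EvaluationReport]:
    """Repeated hold-out on subsampled studies with fixed class ratios."""
    from .simulate import subsample_imbalance

    out = {}
    for i, ratio in enumerate(ratios):
        sub = subsample_imbalance(study, tuple(ratio), seed=seed + i)
        out[f"{ratio[0]}:{ratio[1]}"] = repeated_holdout(
            sub, algorithms, n_runs=n_runs, train_frac=train_frac, seed=seed + i
        )
    return out
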