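"""Posterior-odds Bayesian-network classifier over discretised source scores.

Per source: (1) keep features whose two-sample t-test against the binary
label passes a Bonferroni-corrected 0.05 threshold (falling back to the
single smallest-p feature when none passes); (2) collapse each sample to a
score, the sum of its training-standardised values over the selected
features signed by the direction of the class-mean difference; (3) bin the
scores at the training quartiles (4 bins; boundary values fall in the
lower bin; test samples are binned with the training edges). Per source
pair, an (undirected) dependence edge is added when the within-class
("conditional") correlation of the scores, averaged over the two classes,
exceeds 0.3 in absolute value; the simple (naive) variant forces an empty
edge set. Class-conditional probability tables — joint over each connected
component of the dependence graph, univariate for isolated sources — are
estimated with a Laplace pseudocount so the posterior odds ratio

    Odd_post = Odd_prior * prod_components p(v_comp | y=+1) / p(v_comp | y=-1)

is always finite. Samples with Odd_post > 1 are classified +1, else -1.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import FeatureMatrix, LabelVector, PredictionResult


@dataclass
class SourceScorer:
    """Selected features + directions + standardisation stats for one source."""

    feature_idx: np.ndarray
    directions: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    feature_ids: list[str] = field(default_factory=list)

    def score(self, X: np.ndarray) -> np.ndarray:
        Z = (X[:, self.feature_idx] - self.mean) / self.sd
        return Z @ self.directions


def filter_features(
    X: FeatureMatrix | np.ndarray,
    y_train: LabelVector | np.ndarray,
    alpha: float = 0.05,
) -> SourceScorer:
    """Bonferroni-filtered features with class-difference directions.

    Keeps features with pooled two-sample t-test p < alpha / n_features;
    if none passes, the single smallest-p feature is kept so every source
    always yields a score. Zero-variance features are skipped.
    """
    V = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    fids = X.feature_ids if isinstance(X, FeatureMatrix) else [str(j) for j in range(V.shape[1])]
    yv = y_train.labels if isinstance(y_train, LabelVector) else np.asarray(y_train)
    pos, neg = V[yv == 1], V[yv == -1]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("feature filtering needs training samples of both classes")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(pos, neg, axis=0)
    sd = V.std(axis=0, ddof=1)
    p = np.where(sd > 0, p, np.inf)  # zero-variance: never selected
    n_feat = V.shape[1]
    selected = np.flatnonzero(p < alpha / n_feat)
    if selected.size == 0:
        selected = np.array([int(np.argmin(p))])
    directions = np.sign(pos.mean(axis=0) - neg.mean(axis=0))[selected]
    directions[directions == 0] = 1.0
    mu = V[:, selected].mean(axis=0)
    s = V[:, selected].std(axis=0, ddof=1)
    s = np.where(s > 0, s, 1.0)
    return SourceScorer(selected, directions, mu, s, [fids[j] for j in selected])


def discretize_quartiles(scores_train: np.ndarray, n_bins: int = 4):
    """Training-quartile bin edges; values equal to an edge fall lower.

    Returns (edges, binned_training_scores). Constant scores yield a single
    bin (empty edge list) with a warning.
    """
    scores_train = np.asarray(scores_train, dtype=float)
    if np.ptp(scores_train) == 0:
        warnings.warn("all training scores identical; using a single bin", stacklevel=2)
        edges = np.array([])
    else:
        qs = np.linspace(0, 1, n_bins + 1)[1:-1]
        edges = np.quantile(scores_train, qs)  # linear-interpolation quantiles
    return edges, apply_bins(scores_train, edges)


def apply_bins(scores: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin index in 0..len(edges); score == edge goes to the lower bin."""
    return np.searchsorted(edges, np.asarray(scores, dtype=float), side="left")


def build_structure(
    binned_or_scores: np.ndarray,
    y_train: LabelVector | np.ndarray,
    threshold: float = 0.3,
) -> list[tuple[int, int]]:
    """Dependence edges between source variables.

    For each pair of source-score variables the Pearson correlation is
    computed within each class and averaged; an edge is added when the
    average exceeds ``threshold`` in absolute value.
    """
    V = np.asarray(binned_or_scores, dtype=float)
    yv = y_train.labels if isinstance(y_train, LabelVector) else np.asarray(y_train)
    m = V.shape[1]
    edges = []
    for i, j in itertools.combinations(range(m), 2):
        rs = []
        for cls in (1, -1):
            a, b = V[yv == cls, i], V[yv == cls, j]
            if a.std() == 0 or b.std() == 0:
                rs.append(0.0)
            else:
                rs.append(float(np.corrcoef(a, b)[0, 1]))
        if abs(np.mean(rs)) > threshold:
            edges.append((i, j))
    return edges


def _components(m: int, edges: list[tuple[int, int]]) -> list[list[int]]:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(m))
    g.add_edges_from(edges)
    return [sorted(comp) for comp in nx.connected_components(g)]


@dataclass
class BayesNetClassifier:
    scorers: list[SourceScorer]
    bin_edges: list[np.ndarray]
    structure: list[tuple[int, int]]
    components: list[list[int]]
    cpts: dict  # component tuple -> {+1: table, -1: table}
    prior_odds: float
    n_bins: int
    pseudocount: float

    def transform(self, sources: list[np.ndarray]) -> np.ndarray:
        """Raw per-source matrices -> (n, m) binned score variables."""
        cols = [
            apply_bins(scorer.score(X), edges)
            for scorer, edges, X in zip(self.scorers, self.bin_edges, sources)
        ]
        return np.column_stack(cols)


def fit_bayes_net(
    sources: list[FeatureMatrix | np.ndarray],
    y_train: LabelVector | np.ndarray,
    variant: str = "simple",
    n_bins: int = 4,
    pseudocount: float = 1.0,
    edge_threshold: float = 0.3,
) -> BayesNetClassifier:
    """Fit the full pipeline: filter, score, bin, structure, CPTs, prior."""
    yv = y_train.labels if isinstance(y_train, LabelVector) else np.asarray(y_train)
    mats = [s.values if isinstance(s, FeatureMatrix) else np.asarray(s, dtype=float) for s in sources]
    scorers, edges_list, binned_cols, raw_scores = [], [], [], []
    for X in mats:
        scorer = filter_features(X, yv)
        s = scorer.score(X)
        edges, binned = (
            discretize_quartiles(s, n_bins)[0],
            None,
        )
        scorers.append(scorer)
        edges_list.append(edges)
        binned_cols.append(apply_bins(s, edges))
        raw_scores.append(s)
    binned = np.column_stack(binned_cols)
    m = binned.shape[1]
    if variant == "structured" and m >= 2:
        structure = build_structure(np.column_stack(raw_scores), yv, edge_threshold)
    elif variant in ("simple", "structured"):
        structure = []
    else:
        raise ValueError(f"unknown variant {variant!r}")
    components = _components(m, structure)
    for comp in components:
        if len(comp) > 3:
            warnings.warn(
                f"dependent block of {len(comp)} variables: CPT has {n_bins ** len(comp)} cells",
                stacklevel=2,
            )
    cpts = {}
    for comp in components:
        shape = (n_bins,) * len(comp)
        tables = {}
        for cls in (1, -1):
            counts = np.full(shape, pseudocount, dtype=float)
            for row in binned[yv == cls][:, comp]:
                counts[tuple(row)] += 1.0
            tables[cls] = counts / counts.sum()
        cpts[tuple(comp)] = tables
    n_pos = int((yv == 1).sum())
    n_neg = int((yv == -1).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required to fit the prior odds")
    return BayesNetClassifier(
        scorers, edges_list, structure, components, cpts,
        prior_odds=n_pos / n_neg, n_bins=n_bins, pseudocount=pseudocount,
    )


def posterior_odds(model: BayesNetClassifier, binned: np.ndarray) -> np.ndarray:
    """Odd_post for each row of binned source variables."""
    binned = np.asarray(binned, dtype=int)
    odds = np.full(binned.shape[0], model.prior_odds, dtype=float)
    for comp in model.components:
        tables = model.cpts[tuple(comp)]
        idx = tuple(np.clip(binned[:, comp], 0, model.n_bins - 1).T)
        odds *= tables[1][idx] / tables[-1][idx]
    return odds


def posterior_odds_classify(
    model: BayesNetClassifier, binned: np.ndarray, sample_ids=None
) -> PredictionResult:
    """Classify by Odd_post > 1 (ties -> -1)."""
    odds = posterior_odds(model, binned)
    labels = np.where(odds > 1.0, 1, -1)
    return PredictionResult(labels, odds, "odds", sample_ids)
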