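"""Core containers and I/O for multi-source sample x feature studies.

A *study* is a set of per-source numeric feature matrices over a common,
identically ordered set of samples, a binary phenotype label per sample
(+1 / -1, with 0 reserved internally for samples whose status is hidden
from a fitting routine), and optionally a cluster/family identifier per
sample for cluster-respecting cross-validation.

Matrices live on disk as delimited text (TSV/CSV) with feature ids in the
header row and sample ids in the first column, the processed form in which
omics data are typically exchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ScoreKind = Literal["function_score", "decision_value", "probability", "odds"]


@dataclass
class FeatureMatrix:
    """One omics source: an (n_samples, n_features) numeric matrix."""

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    source_name: str = "source"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-dimensional")
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.feature_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} sample ids x {len(self.feature_ids)} feature ids"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample id")
        if n < 2:
            raise ValueError("a feature matrix needs at least 2 samples")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def restrict(self, sample_ids: Sequence[str]) -> "FeatureMatrix":
        """Return a copy restricted and reordered to ``sample_ids``."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return FeatureMatrix(
            self.values[rows], list(sample_ids), list(self.feature_ids), self.source_name
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


@dataclass
class LabelVector:
    """Binary labels in {-1, +1}; 0 marks samples hidden from fitting."""

    labels: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.labels.ndim != 1 or len(self.labels) != len(self.sample_ids):
            raise ValueError("labels and sample_ids must be equal-length")
        bad = set(np.unique(self.labels)) - {-1, 0, 1}
        if bad:
            raise ValueError(f"labels must lie in {{-1, 0, +1}}, found {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def labelled_mask(self) -> np.ndarray:
        return self.labels != 0

    def require_both_classes(self) -> None:
        lab = self.labels[self.labelled_mask]
        if not ((lab == 1).any() and (lab == -1).any()):
            raise ValueError("both classes must be present among labelled samples")

    def mask(self, hidden_idx: Sequence[int]) -> "LabelVector":
        """Return a copy with labels at ``hidden_idx`` set to 0 (unknown)."""
        lab = self.labels.copy()
        lab[np.asarray(hidden_idx, dtype=int)] = 0
        return LabelVector(lab, list(self.sample_ids))


@dataclass
class MultiOmicsStudy:
    """Aligned per-source matrices + labels (+ optional clusters).

    All sources share ``labels.sample_ids`` in identical order; the label
    file's order is the canonical study order.
    """

    sources: list[FeatureMatrix]
    labels: LabelVector
    clusters: np.ndarray | None = None  # per-sample cluster id (object array)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sources) < 1:
            raise ValueError("a study needs at least one source")
        ids = self.labels.sample_ids
        for src in self.sources:
            if src.sample_ids != ids:
                raise ValueError(f"source {src.source_name!r} is not aligned to the labels")
        if self.clusters is not None:
            self.clusters = np.asarray(self.clusters)
            if len(self.clusters) != len(ids):
                raise ValueError("clusters must give one id per sample")

    @property
    def n_samples(self) -> int:
        return self.labels.n

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def sample_ids(self) -> list[str]:
        return self.labels.sample_ids

    def with_labels(self, labels: LabelVector) -> "MultiOmicsStudy":
        return replace(self, labels=labels)


@dataclass
class PredictionResult:
    """Predicted labels plus the raw per-sample score that produced them."""

    predicted_labels: np.ndarray
    scores: np.ndarray
    score_kind: ScoreKind
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.predicted_labels = np.asarray(self.predicted_labels, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.predicted_labels.shape != self.scores.shape:
            raise ValueError("scores and labels must be the same length")
        if not set(np.unique(self.predicted_labels)) <= {-1, 1}:
            raise ValueError("predicted labels must be in {-1, +1}")
        if self.score_kind == "probability" and (
            (self.scores < 0).any() or (self.scores > 1).any()
        ):
            raise ValueError("probabilities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        ids = self.sample_ids or [str(i) for i in range(len(self.scores))]
        return pd.DataFrame(
            {
                "sample_id": ids,
                "predicted_label": self.predicted_labels,
                "score": self.scores,
                "score_kind": self.score_kind,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# I/O


def _read_table(path, dialect: str | None) -> pd.DataFrame:
    sep = dialect
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str)


def load_feature_matrix(
    path,
    dialect: str | None = None,
    source_name: str | None = None,
    impute: Literal["none", "median"] = "none",
) -> FeatureMatrix:
    """Load a samples x features matrix from delimited text.

    First row holds feature ids, first column sample ids. Parsing is strict:
    a non-numeric cell is an error naming its row and column; missing cells
    are errors unless ``impute="median"``, which fills each with its feature
    (column) median.
    """
    df = _read_table(path, dialect)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r} in {path}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at sample {df.index[i]!r}, feature {df.columns[j]!r} in {path}"
        )
    if numeric.isna().to_numpy().any():
        if impute != "median":
            i, j = np.argwhere(numeric.isna().to_numpy())[0]
            raise ValueError(
                f"missing value at sample {df.index[i]!r}, feature {df.columns[j]!r}; "
                "pass impute='median' to fill from column medians"
            )
        numeric = numeric.fillna(numeric.median(axis=0))
    name = source_name if source_name is not None else _stem(path)
    return FeatureMatrix(
        numeric.to_numpy(dtype=float), list(df.index), list(df.columns), name
    )


def write_feature_matrix(X: FeatureMatrix, path, sep: str = "\t") -> None:
    X.to_frame().to_csv(path, sep=sep)


def load_labels(path, dialect: str | None = None) -> LabelVector:
    """Load a two-column (sample_id, label) file; labels must be -1/+1."""
    sep = dialect or ("," if str(path).endswith(".csv") else "\t")
    df = pd.read_csv(path, sep=sep, header=0)
    if df.shape[1] < 2:
        raise ValueError("labels file needs columns (sample_id, label)")
    ids = df.iloc[:, 0].astype(str).tolist()
    lab = df.iloc[:, 1].astype(int).to_numpy()
    if not set(np.unique(lab)) <= {-1, 1}:
        raise ValueError("labels on disk must be -1 or +1")
    return LabelVector(lab, ids)


def load_clusters(path, dialect: str | None = None) -> pd.Series:
    sep = dialect or ("," if str(path).endswith(".csv") else "\t")
    df = pd.read_csv(path, sep=sep, header=0)
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))


def _stem(path) -> str:
    name = str(path).replace("\\", "/").rsplit("/", 1)[-1]
    return name.rsplit(".", 1)[0]


# ---------------------------------------------------------------------------
# Alignment and scaling


def align_study(
    sources: Sequence[FeatureMatrix],
    labels: LabelVector,
    clusters: pd.Series | None = None,
) -> MultiOmicsStudy:
    """Restrict all inputs to their common samples, in label-file order.

    Samples missing from any source (or from the labels) are dropped and
    logged; an empty intersection is an error, as is an all-unlabelled study.
    """
    common = set(labels.sample_ids)
    for src in sources:
        common &= set(src.sample_ids)
    if clusters is not None:
        common &= set(map(str, clusters.index))
    if not common:
        raise ValueError("no sample is shared by every source and the labels")
    order = [s for s in labels.sample_ids if s in common]
    dropped = [s for s in labels.sample_ids if s not in common]
    if dropped:
        logger.info("align_study dropped %d sample(s): %s", len(dropped), dropped[:10])
    keep = [i for i, s in enumerate(labels.sample_ids) if s in common]
    lab = LabelVector(labels.labels[keep], order)
    if not lab.labelled_mask.any():
        raise ValueError("all labels are 0 after alignment")
    aligned = [src.restrict(order) for src in sources]
    clus = None
    if clusters is not None:
        clus = np.asarray([clusters.loc[s] for s in order])
    return MultiOmicsStudy(aligned, lab, clus)


def zscore_features(
    X: FeatureMatrix,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> FeatureMatrix:
    """Standardize each feature to mean 0, sd 1 (ddof=1).

    Zero-variance features are dropped with a warning. ``stats`` may supply
    externally computed (mean, sd) — e.g. from training samples only — in
    which case no column is dropped and zero sds are replaced by 1.
    """
    V = X.values
    if stats is not None:
        mu, sd = stats
        sd = np.where(sd > 0, sd, 1.0)
        return FeatureMatrix((V - mu) / sd, X.sample_ids, X.feature_ids, X.source_name)
    mu = V.mean(axis=0)
    sd = V.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"{X.source_name}: dropped {int((~keep).sum())} zero-variance feature(s)",
            stacklevel=2,
        )
    Z = (V[:, keep] - mu[keep]) / sd[keep]
    feats = [f for f, k in zip(X.feature_ids, keep) if k]
    return FeatureMatrix(Z, X.sample_ids, feats, X.source_name)


def feature_stats(X: FeatureMatrix, rows: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """(mean, sd ddof=1) of each feature over the given sample rows."""
    V = X.values[np.asarray(rows, dtype=int)]
    return V.mean(axis=0), V.std(axis=0, ddof=1)
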