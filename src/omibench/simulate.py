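"""Synthetic multi-source study generator.

Emulates the structure the integration methods assume: several aligned
feature matrices over the same samples, a binary outcome, a controllable
number of informative features per source whose class means are shifted by
an effect size Delta (in noise-sd units), controllable class imbalance,
and optional family/cluster structure realised as a per-cluster random
intercept shared by every source.

Also implements the class-imbalance subsampling design: draw, without
replacement, the largest sub-study whose positive:negative counts are in
an exact requested integer ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import FeatureMatrix, LabelVector, MultiOmicsStudy


@dataclass
class SourceSpec:
    """One simulated omics source."""

    n_features: int
    n_informative: int = 0
    effect_size: float = 1.0  # class-mean separation Delta, in sd units
    noise_sd: float = 1.0
    name: str | None = None

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")


@dataclass
class SimulationSpec:
    n_samples: int
    sources: list[SourceSpec]
    class_balance: float = 0.5  # fraction of +1 samples
    n_clusters: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.sources = [
            s if isinstance(s, SourceSpec) else SourceSpec(**s) for s in self.sources
        ]
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie strictly between 0 and 1")


def generate_study(spec: SimulationSpec) -> MultiOmicsStudy:
    """Draw a study from a Gaussian class-shift model.

    Informative features have class means +Delta/2 and -Delta/2 (in units of
    their noise sd); all other features are pure noise with mean 0. With
    ``n_clusters`` set, each sample receives an additive cluster intercept
    drawn N(0, (noise_sd/2)^2) per cluster, shared across sources, and
    cluster ids are emitted. Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    n_pos = int(round(n * spec.class_balance))
    n_neg = n - n_pos
    if n_pos < 2 or n_neg < 2:
        raise ValueError(
            f"class_balance={spec.class_balance} leaves fewer than 2 samples in a "
            f"class at n={n} (got {n_pos} positives, {n_neg} negatives)"
        )
    y = np.concatenate([np.ones(n_pos, dtype=int), -np.ones(n_neg, dtype=int)])
    rng.shuffle(y)
    sample_ids = [f"s{i:04d}" for i in range(n)]

    clusters = None
    intercepts = np.zeros(n)
    if spec.n_clusters is not None:
        assignment = rng.integers(0, spec.n_clusters, size=n)
        cluster_effects = {}  # per-cluster effect, drawn per source's noise scale below
        clusters = np.asarray([f"fam{c:02d}" for c in assignment])

    sources = []
    for k, src in enumerate(spec.sources):
        shift = 0.5 * src.effect_size * src.noise_sd
        mean_vec = np.zeros(src.n_features)
        mean_vec[: src.n_informative] = shift
        X = rng.normal(0.0, src.noise_sd, size=(n, src.n_features))
        X += np.outer(y, mean_vec)
        if spec.n_clusters is not None:
            if not cluster_effects:
                raw = rng.normal(0.0, 0.5, size=spec.n_clusters)
                cluster_effects = {c: raw[c] for c in range(spec.n_clusters)}
                intercepts = np.asarray([raw[c] * spec.sources[0].noise_sd for c in assignment])
            X += (np.asarray([cluster_effects[c] for c in assignment]) * src.noise_sd)[:, None]
        name = src.name or f"source{k + 1}"
        feature_ids = [f"{name}_f{j:05d}" for j in range(src.n_features)]
        sources.append(FeatureMatrix(X, sample_ids, feature_ids, name))

    study = MultiOmicsStudy(
        sources, LabelVector(y, sample_ids), clusters=clusters
    )
    study.metadata["spec"] = spec
    if spec.n_clusters is not None:
        study.metadata["cluster_intercepts"] = intercepts
    return study


def subsample_imbalance(
    study: MultiOmicsStudy, ratio: tuple[int, int], seed: int = 0
) -> MultiOmicsStudy:
    """Largest sub-study with positive:negative counts exactly ``ratio``.

    Samples are drawn without replacement. With a positives, b negatives and
    ratio (p, q), the kept counts are (p*k, q*k) for the largest integer k
    with p*k <= a and q*k <= b.
    """
    p_parts, n_parts = ratio
    if p_parts < 1 or n_parts < 1:
        raise ValueError("ratio parts must be positive integers")
    y = study.labels.labels
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == -1)
    k = min(len(pos_idx) // p_parts, len(neg_idx) // n_parts)
    if k < 1:
        raise ValueError(
            f"ratio {p_parts}:{n_parts} unachievable with {len(pos_idx)} positives "
            f"and {len(neg_idx)} negatives (max achievable counts: "
            f"{min(len(pos_idx), p_parts)}:{min(len(neg_idx), n_parts)} scaled down)"
        )
    n_pos, n_neg = p_parts * k, n_parts * k
    rng = np.random.default_rng(seed)
    keep = np.sort(
        np.concatenate(
            [
                rng.choice(pos_idx, size=n_pos, replace=False),
                rng.choice(neg_idx, size=n_neg, replace=False),
            ]
        )
    )
    ids = [study.sample_ids[i] for i in keep]
    sources = [src.restrict(ids) for src in study.sources]
    labels = LabelVector(y[keep], ids)
    clusters = study.clusters[keep] if study.clusters is not None else None
    return MultiOmicsStudy(sources, labels, clusters=clusters)
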