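"""Unsupervised discovery of behavior groups from binned features.

The pipeline standardizes the feature columns (px and degrees are not
commensurate), picks the embedding dimensionality as the smallest number of
principal components explaining >= 70% of variance, embeds with UMAP
(n_neighbors=60, min_dist=0.0, Euclidean metric — parameters chosen for
clustering rather than visualization), and clusters the embedding with
HDBSCAN, whose density hierarchy leaves low-density bins unassigned (-1)
instead of forcing them into a group. Noise bins are excluded when the
downstream classifier is trained, purifying its training set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import joblib
import numpy as np
from sklearn.cluster import HDBSCAN
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

import umap

from .errors import InsufficientDataError, ParameterError
from .features import FeatureMatrix

__all__ = [
    "SegmentationModel",
    "choose_dimensionality",
    "embed",
    "cluster",
    "fit_segmentation",
]


@dataclass
class SegmentationModel:
    """Fitted segmentation state: scaler, dimensionality, embedding, labels."""

    scaler: StandardScaler
    n_components: int
    umap_state: Any
    embedding: np.ndarray
    cluster_labels: np.ndarray
    feature_names: list[str]
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def n_groups(self) -> int:
        return int((np.unique(self.cluster_labels) >= 0).sum())

    @property
    def soft_assign_fraction(self) -> float:
        """Fraction of bins assigned to a group (not labelled noise)."""
        return float((self.cluster_labels >= 0).mean())

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "SegmentationModel":
        return joblib.load(path)


def _standardized(features: FeatureMatrix, scaler: StandardScaler | None = None):
    x = features.values
    if scaler is None:
        scaler = StandardScaler().fit(x)
    # constant columns get unit scale so they map to 0, not NaN
    scaler.scale_[scaler.scale_ == 0] = 1.0
    return scaler.transform(x), scaler


def choose_dimensionality(
    features: FeatureMatrix, variance_target: float = 0.7
) -> int:
    """Smallest d whose top principal components explain >= the target.

    Computed on z-scored columns; at least 2 dimensions are returned so the
    embedding always has a meaningful geometry.
    """
    if features.n_bins < 3:
        raise InsufficientDataError(
            f"need at least 3 bins to estimate dimensionality, got {features.n_bins}"
        )
    x, _ = _standardized(features)
    pca = PCA().fit(x)
    cum = np.cumsum(pca.explained_variance_ratio_)
    d = int(np.searchsorted(cum, variance_target) + 1)
    return max(d, 2)


def embed(
    features: FeatureMatrix,
    d: int,
    seed: int,
    n_neighbors: int = 60,
    min_dist: float = 0.0,
    metric: str = "euclidean",
    scaler: StandardScaler | None = None,
):
    """UMAP-embed standardized features into d dimensions.

    Returns ``(embedding, reducer, scaler)``. The fitted reducer is kept
    for audit; prediction on new sessions goes through the classifier, not
    through re-embedding.
    """
    if features.n_bins <= n_neighbors:
        raise ParameterError(
            f"{features.n_bins} bins <= n_neighbors={n_neighbors}; "
            "use a longer session or a smaller n_neighbors"
        )
    x, scaler = _standardized(features, scaler)
    reducer = umap.UMAP(
        n_components=d,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        metric=metric,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # umap warns that a fixed random_state disables parallelism
        warnings.filterwarnings("ignore", module="umap")
        warnings.filterwarnings("ignore", category=UserWarning)
        embedding = reducer.fit_transform(x)
    return np.asarray(embedding), reducer, scaler


def cluster(embedding: np.ndarray, min_cluster_size: float | int = 0.01) -> np.ndarray:
    """HDBSCAN group assignment on the embedding; -1 marks noise bins.

    ``min_cluster_size`` below 1 is read as a fraction of the number of
    bins (default 1%) and converted with a ceiling.
    """
    b = embedding.shape[0]
    if 0 < min_cluster_size < 1:
        mcs = int(np.ceil(min_cluster_size * b))
    else:
        mcs = int(min_cluster_size)
    if mcs < 2:
        mcs = 2
    if mcs > b:
        raise ParameterError(
            f"min_cluster_size={mcs} exceeds the {b} available bins"
        )
    # allow the hierarchy root as a cluster: a unimodal embedding is one
    # behavior group, not all noise
    labels = HDBSCAN(
        min_cluster_size=mcs, allow_single_cluster=True, copy=True
    ).fit_predict(np.asarray(embedding, dtype=np.float64))
    if (labels < 0).all():
        raise ParameterError(
            "HDBSCAN labelled every bin as noise; try a smaller min_cluster_size"
        )
    return labels


def fit_segmentation(
    features: FeatureMatrix,
    seed: int,
    variance_target: float = 0.7,
    n_neighbors: int = 60,
    min_dist: float = 0.0,
    metric: str = "euclidean",
    min_cluster_size: float | int = 0.01,
) -> SegmentationModel:
    """Full unsupervised path: standardize -> PCA criterion -> UMAP -> HDBSCAN."""
    d = choose_dimensionality(features, variance_target)
    embedding, reducer, scaler = embed(
        features, d, seed, n_neighbors=n_neighbors, min_dist=min_dist, metric=metric
    )
    labels = cluster(embedding, min_cluster_size)
    noise_frac = float((labels < 0).mean())
    if noise_frac > 0.5:
        warnings.warn(
            f"{noise_frac:.0%} of bins labelled noise; clusters may be poorly "
            "separated or min_cluster_size too large",
            stacklevel=2,
        )
    return SegmentationModel(
        scaler=scaler,
        n_components=d,
        umap_state=reducer,
        embedding=embedding,
        cluster_labels=labels,
        feature_names=list(features.feature_names),
        seed=seed,
        config=dict(
            variance_target=variance_target,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            metric=metric,
            min_cluster_size=min_cluster_size,
        ),
    )
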