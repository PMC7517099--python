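"""Vector quantization of feature vectors into discrete codebook symbols.

The codebook is a k-means clustering of (standardized) multifused feature
vectors; a window's symbol is the index of its nearest centroid.  The
implementation is deliberately self-contained and deterministic: the
first centre is drawn from the given seed, the remaining centres are
placed by farthest-point selection, and Lloyd iterations proceed until
the centroid shift drops below ``tol`` or ``max_iter`` is reached.  The
within-cluster distortion is checked to be non-increasing at every step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass
class Codebook:
    """K centroids mapping feature vectors to symbols 0..K-1."""

    centroids: np.ndarray  # (K, D)
    seed: int
    feature_layout: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.ndim != 2 or self.centroids.shape[0] < 2:
            raise ValueError("a codebook needs a (K>=2, D) centroid matrix")

    @property
    def n_symbols(self) -> int:
        return self.centroids.shape[0]


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, np.ndarray):
        return np.asarray(features, dtype=float)
    return np.stack([np.asarray(getattr(f, "values", f), dtype=float)
                     for f in features])


def _kmeans(X: np.ndarray, k: int, seed: int, max_iter: int, tol: float):
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    # farthest-point (k-means++-style) seeding: random first centre, then
    # repeatedly the point farthest from its nearest chosen centre.
    chosen = [int(rng.integers(n))]
    d_min = np.linalg.norm(X - X[chosen[0]], axis=1)
    while len(chosen) < k:
        nxt = int(np.argmax(d_min))  # ties -> lowest index
        chosen.append(nxt)
        d_min = np.minimum(d_min, np.linalg.norm(X - X[nxt], axis=1))
    centers = X[chosen].copy()

    prev_distortion = np.inf
    for _ in range(max_iter):
        dist = cdist(X, centers)
        assign = np.argmin(dist, axis=1)  # ties -> lowest index
        distortion = float((dist[np.arange(n), assign] ** 2).sum())
        if distortion > prev_distortion + 1e-8 * max(1.0, prev_distortion):
            raise AssertionError("k-means distortion increased")
        prev_distortion = distortion
        new_centers = centers.copy()
        for j in range(k):
            members = assign == j
            if members.any():
                new_centers[j] = X[members].mean(axis=0)
        # an emptied cluster is re-seeded on the worst-fit point
        for j in range(k):
            if not (assign == j).any():
                worst = int(np.argmax(dist[np.arange(n), assign]))
                new_centers[j] = X[worst]
        shift = float(np.linalg.norm(new_centers - centers, axis=1).max())
        centers = new_centers
        if shift < tol:
            break
    return centers


def build_codebook(features, k: int, seed: int, max_iter: int = 300,
                   tol: float = 1e-6, feature_layout=None) -> Codebook:
    """Fit a K-symbol codebook on a collection of feature vectors.

    Requires at least ``k`` distinct vectors; deterministic for fixed
    (features, k, seed).
    """
    X = _as_matrix(features)
    if k < 2:
        raise ValueError("k must be >= 2")
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError(f"need at least {k} distinct feature vectors")
    centers = _kmeans(X, k, seed, max_iter, tol)
    return Codebook(centroids=centers, seed=seed,
                    feature_layout=list(feature_layout or []))


def quantize(feature, codebook: Codebook) -> int:
    """Index of the nearest centroid (Euclidean); ties -> lowest index."""
    x = np.asarray(getattr(feature, "values", feature), dtype=float)
    if x.ndim == 1:
        if x.size != codebook.centroids.shape[1]:
            raise ValueError(
                f"feature dimension {x.size} != codebook dimension "
                f"{codebook.centroids.shape[1]}"
            )
        return int(np.argmin(np.linalg.norm(codebook.centroids - x, axis=1)))
    if x.shape[1] != codebook.centroids.shape[1]:
        raise ValueError("feature dimension mismatch")
    return np.argmin(cdist(x, codebook.centroids), axis=1)


def save_codebook(codebook: Codebook, csv_path, meta_path=None) -> Path:
    """Serialize centroids as CSV (one per row) plus JSON metadata."""
    csv_path = Path(csv_path)
    np.savetxt(csv_path, codebook.centroids, delimiter=",", fmt="%.17g")
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".json")
    with open(meta_path, "w") as fh:
        json.dump(
            {
                "n_symbols": codebook.n_symbols,
                "seed": codebook.seed,
                "feature_layout": [list(t) for t in codebook.feature_layout],
            },
            fh,
            indent=2,
        )
    return csv_path


def load_codebook(csv_path, meta_path=None) -> Codebook:
    csv_path = Path(csv_path)
    centroids = np.loadtxt(csv_path, delimiter=",", ndmin=2)
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".json")
    with open(meta_path) as fh:
        meta = json.load(fh)
    return Codebook(
        centroids=centroids,
        seed=int(meta["seed"]),
        feature_layout=[tuple(t) for t in meta.get("feature_layout", [])],
    )


class CodebookQuantizer(BaseEstimator, TransformerMixin):
    """Transformer mapping feature rows to discrete symbol indices.

    Parameters
    ----------
    n_symbols : int, default 64
        Codebook size K.  The symbol space should comfortably exceed the
        number of activity classes.
    random_state : int, default 0
        Seed for the (otherwise deterministic) centre initialization.
    max_iter : int, default 300
        Lloyd iteration cap.
    tol : float, default 1e-6
        Centroid-shift convergence threshold.

    Attributes
    ----------
    codebook_ : Codebook
    cluster_centers_ : ndarray of shape (n_symbols, n_features)
    """

    def __init__(self, n_symbols: int = 64, random_state: int = 0,
                 max_iter: int = 300, tol: float = 1e-6):
        self.n_symbols = n_symbols
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        self.codebook_ = build_codebook(
            X, k=self.n_symbols, seed=self.random_state,
            max_iter=self.max_iter, tol=self.tol,
        )
        self.cluster_centers_ = self.codebook_.centroids
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "codebook_"):
            raise RuntimeError("CodebookQuantizer is not fitted")
        return quantize(_as_matrix(X), self.codebook_)
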