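"""Fuzzy c-means clustering of standardized expression profiles.

Profiles (exon counts, event inclusion levels, or gene counts, one row per
feature across samples) are standardized to mean 0 / sd 1 per row and
soft-clustered with fuzzy c-means (fuzzifier m, default 2).  The number of
clusters is selected from the minimum-centroid-distance curve over
k = 2..20: the selected k sits just before the sharpest drop (maximal
forward second difference of the curve).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_random_state

log = logging.getLogger(__name__)

__all__ = ["standardize_rows", "FuzzyCMeans", "fuzzy_cmeans", "DminCurve", "select_k_dmin"]


def standardize_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each row to mean 0, sample sd 1 (n-1 denominator).

    Zero-variance rows are dropped with a log message.  Standardizing twice
    is idempotent.
    """
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    keep = sd[:, 0] > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("standardize_rows: dropped %d zero-variance rows", n_dropped)
    out = (values[keep] - mean[keep]) / sd[keep]
    return pd.DataFrame(out, index=matrix.index[keep], columns=matrix.columns)


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy c-means clustering.

    Alternates membership^m-weighted center updates with inverse-distance
    membership updates (exponent 2/(m-1)) until the largest center shift
    falls below ``tol``.  The objective sum(u^m d^2) is non-increasing over
    iterations.  Deterministic given ``random_state``.

    Parameters
    ----------
    n_clusters : int
        Number of clusters k (k = 1 degenerates to the data mean).
    m : float
        Fuzzifier, > 1; larger values give softer memberships.
    tol : float
        Convergence threshold on the maximum center shift.
    max_iter : int
        Iteration cap.
    random_state : int, RandomState or None
        Seeds the center initialization (k distinct data points).

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (k, n_features)
    membership_ : ndarray of shape (n_samples, k); rows sum to 1
    labels_ : hard assignment (argmax membership)
    objective_ : final objective value
    n_iter_ : iterations run
    """

    def __init__(self, n_clusters=2, m=2.0, tol=1e-6, max_iter=500, random_state=None):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def _memberships(self, x: np.ndarray, centers: np.ndarray) -> np.ndarray:
        d2 = cdist(x, centers, "sqeuclidean")
        exp = 1.0 / (self.m - 1.0)
        zero = d2 <= 1e-300
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = (1.0 / d2) ** exp
            u = inv / inv.sum(axis=1, keepdims=True)
        rows_on_center = zero.any(axis=1)
        if rows_on_center.any():
            u[rows_on_center] = zero[rows_on_center] / zero[rows_on_center].sum(axis=1, keepdims=True)
        return u

    def fit(self, X, y=None):
        x = check_array(X, dtype=float)
        k = int(self.n_clusters)
        if k < 1:
            raise ValueError("n_clusters must be >= 1")
        if k > x.shape[0]:
            raise ValueError(f"n_clusters={k} exceeds number of rows {x.shape[0]}")
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if k == 1:
            self.cluster_centers_ = x.mean(axis=0, keepdims=True)
            self.membership_ = np.ones((x.shape[0], 1))
            self.labels_ = np.zeros(x.shape[0], dtype=int)
            self.objective_ = float(np.sum(cdist(x, self.cluster_centers_, "sqeuclidean")))
            self.n_iter_ = 0
            return self
        rng = check_random_state(self.random_state)
        centers = x[rng.choice(x.shape[0], size=k, replace=False)].copy()
        for it in range(1, int(self.max_iter) + 1):
            u = self._memberships(x, centers)
            w = u**self.m
            new_centers = (w.T @ x) / w.sum(axis=0)[:, None]
            shift = float(np.max(np.abs(new_centers - centers)))
            centers = new_centers
            if shift < self.tol:
                break
        self.cluster_centers_ = centers
        self.membership_ = self._memberships(x, centers)
        self.labels_ = self.membership_.argmax(axis=1)
        d2 = cdist(x, centers, "sqeuclidean")
        self.objective_ = float(np.sum(self.membership_**self.m * d2))
        self.n_iter_ = it
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        x = check_array(X, dtype=float)
        return self._memberships(x, self.cluster_centers_).argmax(axis=1)

    def predict_membership(self, X):
        check_is_fitted(self, "cluster_centers_")
        x = check_array(X, dtype=float)
        return self._memberships(x, self.cluster_centers_)


def fuzzy_cmeans(
    data, k: int, m: float = 2.0, seed: int | None = None, tol: float = 1e-6, max_iter: int = 500
) -> FuzzyCMeans:
    """Functional wrapper over :class:`FuzzyCMeans` (rows are features)."""
    x = data.to_numpy(dtype=float) if isinstance(data, pd.DataFrame) else np.asarray(data, float)
    return FuzzyCMeans(n_clusters=k, m=m, tol=tol, max_iter=max_iter, random_state=seed).fit(x)


@dataclass
class DminCurve:
    ks: np.ndarray
    dmin: np.ndarray
    selected_k: int
    fallback: bool = False


def min_centroid_distance(centers: np.ndarray) -> float:
    d = cdist(centers, centers)
    iu = np.triu_indices(len(centers), k=1)
    return float(d[iu].min())


def select_k_dmin(
    data,
    k_range=range(2, 21),
    m: float = 2.0,
    seed: int | None = None,
    flat_tol: float = 1e-8,
) -> DminCurve:
    """Minimum-centroid-distance curve with inflection-based k selection.

    For each k the minimum pairwise Euclidean distance between fitted
    centers is recorded.  The selected k maximizes the forward second
    difference ``Dmin(k) - 2 Dmin(k+1) + Dmin(k+2)`` — the k just before
    the sharpest drop of the curve.  A flat/linear curve (all second
    differences below ``flat_tol``) falls back to the smallest k with a
    warning.
    """
    ks = np.array(sorted(k_range), dtype=int)
    if len(ks) < 3:
        raise ValueError("k range must contain at least 3 values")
    dmin = np.empty(len(ks))
    for i, k in enumerate(ks):
        model = fuzzy_cmeans(data, int(k), m=m, seed=seed)
        dmin[i] = min_centroid_distance(model.cluster_centers_)
    second = dmin[:-2] - 2.0 * dmin[1:-1] + dmin[2:]
    if np.max(second) < flat_tol:
        log.warning("Dmin curve has no inflection; falling back to k = %d", ks[0])
        return DminCurve(ks, dmin, int(ks[0]), fallback=True)
    selected = int(ks[int(np.argmax(second))])
    return DminCurve(ks, dmin, selected)
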