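"""Fuzzy c-means clustering of nutrient-response coefficient vectors.

Each diet-responsive feature (gene or exon) is summarized by its three
no-intercept model coefficients (per percent fat, carb, protein).  Row-wise
centering and scaling removes expression magnitude so that clustering
reflects response *topology*: which nutrient gradients drive the feature.
Soft (fuzzy) clustering with the classic Bezdek alternating updates then
groups features; each feature is assigned to its maximum-membership cluster
and a cluster surface is fitted from the mean scaled expression/usage of its
members.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .design import DietDesign, RmtGrid
from .expression import NutrientCoefficients
from .surfaces import ResponseSurface, fit_surface_response, predict_surface

__all__ = [
    "FuzzyCMeans",
    "FuzzyClusterModel",
    "scale_coefficients",
    "fuzzy_cmeans",
    "assign_clusters",
    "cluster_surface",
]

log = logging.getLogger(__name__)


def scale_coefficients(
    coeffs: list[NutrientCoefficients] | np.ndarray,
    mode: str = "per_feature",
    drop_degenerate: bool = True,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Center and scale coefficient vectors before clustering.

    ``per_feature`` (default) z-scores each 3-vector across its own entries
    (sample sd over the 3 values), so only the response shape survives;
    ``per_coefficient`` z-scores each coefficient column across features.
    Returns (matrix, kept_feature_ids, dropped_feature_ids); features whose
    three coefficients are equal are degenerate under per-feature scaling and
    are dropped (logged) by default.
    """
    if isinstance(coeffs, np.ndarray):
        mat = np.asarray(coeffs, dtype=float)
        ids = [f"f{i}" for i in range(mat.shape[0])]
    else:
        mat = np.array([c.vector for c in coeffs], dtype=float)
        ids = [c.feature_id for c in coeffs]
    if mat.ndim != 2 or mat.shape[1] != 3:
        raise ValueError("coefficient matrix must be (n_features, 3)")
    if not np.all(np.isfinite(mat)):
        raise ValueError("coefficients must be finite")
    dropped: list[str] = []
    if mode == "per_feature":
        mu = mat.mean(axis=1, keepdims=True)
        sd = mat.std(axis=1, ddof=1, keepdims=True)
        degenerate = sd.ravel() <= 1e-12
        scaled = np.where(sd > 1e-12, (mat - mu) / np.where(sd > 1e-12, sd, 1.0), 0.0)
        if np.any(degenerate):
            dropped = [i for i, d in zip(ids, degenerate) if d]
            log.info("scale_coefficients: %d degenerate features", len(dropped))
            if drop_degenerate:
                scaled = scaled[~degenerate]
                ids = [i for i, d in zip(ids, degenerate) if not d]
    elif mode == "per_coefficient":
        mu = mat.mean(axis=0, keepdims=True)
        sd = mat.std(axis=0, ddof=1, keepdims=True)
        scaled = (mat - mu) / np.where(sd > 1e-12, sd, 1.0)
    else:
        raise ValueError("mode must be 'per_feature' or 'per_coefficient'")
    return scaled, ids, dropped


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy c-means (Bezdek) clustering with canonicalized cluster order.

    Alternating updates of memberships u_ij = 1 / Σ_l (d_ij/d_lj)^(2/(m−1))
    (Euclidean d) and centers c_i = Σ_j u_ij^m x_j / Σ_j u_ij^m, iterated
    until the objective Σ u^m d² changes by less than ``tol``.  A point that
    coincides with a center takes membership 1 there (limit convention).
    Cluster labels are canonicalized by sorting centers lexicographically.

    Parameters
    ----------
    n_clusters : int, default 5
    m : float, fuzzifier, must be > 1 (2 is the conventional default)
    n_init : int
        Random restarts; the run with the lowest final objective is kept
        (the alternating updates only find local optima).
    """

    def __init__(
        self,
        n_clusters: int = 5,
        m: float = 2.0,
        tol: float = 1e-9,
        max_iter: int = 1000,
        n_init: int = 10,
        random_state: int | None = None,
        debug_checks: bool = False,
    ):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.random_state = random_state
        self.debug_checks = debug_checks

    def _memberships(self, X: np.ndarray, centers: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 1e-300
        u = np.empty((X.shape[0], centers.shape[0]))
        power = 1.0 / (self.m - 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-power)
        rows_zero = zero.any(axis=1)
        u[~rows_zero] = inv[~rows_zero] / inv[~rows_zero].sum(axis=1, keepdims=True)
        if np.any(rows_zero):
            u[rows_zero] = 0.0
            z = zero[rows_zero]
            u[rows_zero] = z / z.sum(axis=1, keepdims=True)
        return u

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n = X.shape[0]
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.n_clusters >= n:
            raise ValueError("need more points than clusters")
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        rng = np.random.default_rng(self.random_state)
        # initialize at k distinct data points
        uniq = np.unique(X, axis=0)
        if uniq.shape[0] < self.n_clusters:
            raise ValueError("fewer distinct points than clusters")
        best = None
        for _ in range(max(self.n_init, 1)):
            centers0 = uniq[rng.choice(uniq.shape[0], self.n_clusters, replace=False)]
            centers, u, obj, it = self._run(X, centers0)
            if best is None or obj < best[2]:
                best = (centers, u, obj, it)
        centers, u, prev_obj, it = best
        # canonical order: lexicographic on center coordinates
        order = np.lexsort(tuple(centers[:, c] for c in range(X.shape[1] - 1, -1, -1)))
        centers = centers[order]
        u = u[:, order]
        labels, ties = _argmax_low_index(u)
        self.cluster_centers_ = centers
        self.membership_ = u
        self.labels_ = labels
        self.tie_count_ = ties
        self.objective_ = prev_obj
        self.n_iter_ = it
        return self

    def _run(self, X, centers):
        prev_obj = np.inf
        u = self._memberships(X, centers)
        it = 0
        for it in range(1, self.max_iter + 1):
            um = u**self.m
            centers = (um.T @ X) / um.sum(axis=0)[:, None]
            u = self._memberships(X, centers)
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            obj = float(((u**self.m) * d2).sum())
            if self.debug_checks:
                assert obj <= prev_obj + 1e-9, "objective increased"
            if abs(prev_obj - obj) < self.tol:
                prev_obj = obj
                break
            prev_obj = obj
        return centers, u, prev_obj, it

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        u = self._memberships(np.asarray(X, dtype=float), self.cluster_centers_)
        return _argmax_low_index(u)[0]

    def soft_predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        return self._memberships(np.asarray(X, dtype=float), self.cluster_centers_)

    @property
    def partition_coefficient_(self) -> float:
        """Fuzzy partition coefficient (1/n)ΣΣ u²; 1 = crisp, 1/k = uniform."""
        check_is_fitted(self, "membership_")
        return float((self.membership_**2).sum() / self.membership_.shape[0])


def _argmax_low_index(u: np.ndarray) -> tuple[np.ndarray, int]:
    labels = np.argmax(u, axis=1)  # argmax takes the lowest index on ties
    row_max = u[np.arange(u.shape[0]), labels]
    ties = int(((u >= row_max[:, None] - 1e-15).sum(axis=1) > 1).sum())
    return labels, ties


@dataclass
class FuzzyClusterModel:
    """Fitted fuzzy clustering of feature coefficient vectors."""

    k: int
    m: float
    centers: np.ndarray
    membership: np.ndarray
    objective: float
    assignments: dict[str, int]
    feature_ids: list[str]
    seed: int | None
    n_iter: int
    tie_count: int = 0

    def membership_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.membership,
            index=self.feature_ids,
            columns=[f"cluster_{i}" for i in range(self.k)],
        )


def fuzzy_cmeans(
    X: np.ndarray,
    k: int,
    m: float = 2.0,
    tol: float = 1e-9,
    max_iter: int = 1000,
    seed: int | None = None,
    feature_ids: list[str] | None = None,
) -> FuzzyClusterModel:
    """Cluster scaled coefficient vectors; see :class:`FuzzyCMeans`."""
    est = FuzzyCMeans(
        n_clusters=k, m=m, tol=tol, max_iter=max_iter, random_state=seed
    ).fit(X)
    ids = feature_ids or [f"f{i}" for i in range(np.asarray(X).shape[0])]
    return FuzzyClusterModel(
        k=k,
        m=m,
        centers=est.cluster_centers_,
        membership=est.membership_,
        objective=est.objective_,
        assignments=dict(zip(ids, est.labels_.tolist())),
        feature_ids=ids,
        seed=seed,
        n_iter=est.n_iter_,
        tie_count=est.tie_count_,
    )


def assign_clusters(model: FuzzyClusterModel) -> dict[str, int]:
    """Maximum-membership hard assignment (ties go to the lowest index)."""
    labels, ties = _argmax_low_index(model.membership)
    if ties:
        log.info("assign_clusters: %d membership ties", ties)
    return dict(zip(model.feature_ids, labels.tolist()))


def cluster_surface(
    assignments: dict[str, int],
    values: pd.DataFrame,
    design: DietDesign,
    grid: RmtGrid,
    orders=("null", "linear", "quadratic"),
) -> dict[int, ResponseSurface]:
    """Mean-member response surface per cluster.

    ``values`` is a feature × sample matrix of centered/scaled expression or
    usage; per cluster, the per-sample mean over member features is fitted
    with the AIC-selected Scheffé polynomial and predicted over ``grid``.
    """
    clusters = sorted(set(assignments.values()))
    surfaces: dict[int, ResponseSurface] = {}
    for c in clusters:
        members = [f for f, lab in assignments.items() if lab == c]
        members = [f for f in members if f in values.index]
        if not members:
            warnings.warn(f"cluster {c} has no members with values; skipped")
            continue
        mean_vals = values.loc[members].mean(axis=0)
        y = mean_vals.loc[design.sample_ids].to_numpy(dtype=float)
        fit = fit_surface_response(y, design, orders=orders)
        fit.response_name = f"cluster_{c}"
        surfaces[c] = predict_surface(fit, grid)
    return surfaces
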