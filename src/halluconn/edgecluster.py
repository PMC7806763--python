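"""K-means clustering of component edges by their group-level behavior.

Each edge of a cross-group NBS component is summarized by its
covariate-adjusted mean connectivity per group (its *profile*); profiles
are clustered with best-of-restarts k-means (k = 6 by default, matching the
six connection sets the reference analysis reports).  Profiles are not
standardized per edge by default: clusters are meant to distinguish
increased from decreased connectivity levels, which per-edge z-scoring
would erase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from ._edges import canonical_edge, edge_index, vectorize_matrices
from .connectome import as_weight_stack
from .nbs import _adjusted_group_means


def edge_profiles(
    component_edges,
    matrices,
    subjects: pd.DataFrame,
    groups: list[str],
    covariates: tuple[str, ...] = ("age", "sex"),
) -> pd.DataFrame:
    """Adjusted group-mean connectivity per component edge.

    Rows are component edges (canonical order), columns the declared group
    order; entries come from the same cell-means linear model used for NBS
    direction labeling (plain group means when ``covariates`` is empty).
    """
    edges = sorted(canonical_edge(*e) for e in component_edges)
    if not edges:
        raise ValueError("empty component")
    stack = as_weight_stack(matrices)
    subjects = subjects.reset_index(drop=True)
    missing = [g for g in groups if g not in set(subjects["group"])]
    if missing:
        raise ValueError(f"groups {missing} absent from subject table")
    keep = subjects["group"].isin(groups).to_numpy()
    stack, sub = stack[keep], subjects.loc[keep].reset_index(drop=True)
    Y = vectorize_matrices(stack)
    means = _adjusted_group_means(Y, sub, list(covariates))
    iu, ju = edge_index(stack.shape[1])
    eidx = {(int(i), int(j)): k for k, (i, j) in enumerate(zip(iu, ju))}
    cols = [eidx[e] for e in edges]
    prof = means.loc[groups, cols].T
    prof.index = pd.Index([f"{i}--{j}" for i, j in edges], name="edge")
    return prof


class EdgeKMeans(BaseEstimator):
    """Best-of-restarts Lloyd k-means over edge profiles with canonical labels.

    Cluster ids are renumbered by (size descending, first-group centroid
    value) so repeated runs and row permutations yield the same labeling.
    """

    def __init__(self, k: int = 6, n_restarts: int = 50, random_state: int = 0, zscore: bool = False):
        self.k = k
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.zscore = zscore

    def fit(self, profiles: pd.DataFrame):
        X = np.asarray(profiles, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("profiles must be a nonempty 2-D table")
        if not 1 <= self.k <= X.shape[0]:
            raise ValueError(f"k={self.k} must be in [1, n_edges={X.shape[0]}]")
        Z = X
        if self.zscore:
            sd = X.std(axis=1, keepdims=True)
            Z = (X - X.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
        km = KMeans(
            n_clusters=self.k, n_init=self.n_restarts, init="k-means++",
            algorithm="lloyd", random_state=self.random_state,
        ).fit(Z)
        labels, centroids = km.labels_, km.cluster_centers_
        sizes = np.bincount(labels, minlength=self.k)
        order = sorted(range(self.k), key=lambda c: (-sizes[c], -centroids[c, 0]))
        remap = {old: new for new, old in enumerate(order)}
        self.labels_ = np.array([remap[c] for c in labels])
        self.cluster_centers_ = centroids[order]
        self.inertia_ = float(km.inertia_)
        self.profiles_ = profiles if isinstance(profiles, pd.DataFrame) else pd.DataFrame(X)
        return self

    def fit_predict(self, profiles: pd.DataFrame) -> np.ndarray:
        return self.fit(profiles).labels_

    def summary(self) -> pd.DataFrame:
        """Per-cluster, per-group mean and SD of profiles (error-bar data)."""
        prof = self.profiles_
        rows = []
        for c in range(self.k):
            sel = prof.iloc[self.labels_ == c]
            for g in prof.columns:
                rows.append(dict(cluster=c, group=g, n_edges=len(sel),
                                 mean=float(sel[g].mean()), sd=float(sel[g].std(ddof=0))))
        return pd.DataFrame(rows)


def kmeans_cluster(profiles: pd.DataFrame, k: int = 6, seed: int = 0, n_restarts: int = 50):
    """Convenience wrapper returning (labels, centroids, within-cluster SS)."""
    est = EdgeKMeans(k=k, n_restarts=n_restarts, random_state=seed).fit(profiles)
    return est.labels_, est.cluster_centers_, est.inertia_


def select_k_silhouette(profiles: pd.DataFrame, k_range=range(2, 9), seed: int = 0) -> int:
    """Optional silhouette-based choice of k (off by default in the pipeline)."""
    X = np.asarray(profiles, dtype=float)
    best_k, best_s = None, -np.inf
    for k in k_range:
        if k >= X.shape[0]:
            break
        labels = EdgeKMeans(k=k, random_state=seed).fit_predict(profiles)
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(X, labels)
        if s > best_s:
            best_k, best_s = k, s
    if best_k is None:
        raise ValueError("too few edges to select k")
    return best_k
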