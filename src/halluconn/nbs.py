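"""Network-Based Statistics: covariate-adjusted edge F-tests with
permutation family-wise-error control over connected components.

For every edge the weight is modelled as ``weight ~ group + covariates`` and
the partial F for the group factor computed (for two groups without
covariates this equals the squared pooled-variance t).  Edges with F at or
above the primary threshold form a graph whose connected components are the
candidate subnetworks; each component's extent (edge count) is referred to
the permutation distribution of the *maximum* component extent, giving an
FWE-adjusted p-value

    p_FWE = (1 + #{perm max extent >= observed extent}) / (1 + n_perm).

Nuisance covariates are handled by Freedman-Lane permutation by default:
the residuals of the covariates-only model are permuted, the reduced fit
added back, and the full-model F recomputed, so covariates stay attached to
their subjects.  Plain group-label permutation is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._edges import edge_index, vectorize_matrices
from .connectome import as_weight_stack

_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class NBSConfig:
    primary_threshold: float = 8.0
    n_permutations: int = 10_000
    covariates: tuple[str, ...] = ("age", "sex")
    alpha: float = 0.05
    permutation: str = "freedman-lane"  # or "labels"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.primary_threshold <= 0:
            raise ValueError("primary threshold must be positive")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")
        if self.permutation not in ("freedman-lane", "labels"):
            raise ValueError("permutation must be 'freedman-lane' or 'labels'")


@dataclass
class Component:
    edges: list[tuple[int, int]]
    nodes: list[int]
    extent: int
    fwe_p: float = np.nan


@dataclass
class NBSResult:
    groups: list[str]
    edge_fstats: np.ndarray          # per canonical edge
    degenerate_edges: np.ndarray     # bool flags (constant edges, F set to 0)
    adjusted_means: pd.DataFrame     # groups x edges, covariate-adjusted
    components: list[Component]
    edge_direction: dict[tuple[int, int], str]  # suprathreshold edges only
    null_max_extent: np.ndarray
    threshold: float
    alpha: float

    @property
    def significant_components(self) -> list[Component]:
        return [c for c in self.components if c.fwe_p < self.alpha]


def _covariate_columns(subjects: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    cols = []
    for c in covariates:
        v = subjects[c]
        if v.dtype.kind in "ifu":
            cols.append(v.to_numpy(dtype=float))
        else:  # categorical covariate -> dummies, first level dropped
            d = pd.get_dummies(v, drop_first=True)
            cols.extend(d[k].to_numpy(dtype=float) for k in d.columns)
    if not cols:
        return np.empty((len(subjects), 0))
    return np.column_stack(cols)


def _design_matrices(subjects: pd.DataFrame, covariates: list[str]):
    """Full ([1 | group dummies | covariates]) and reduced ([1 | covariates])
    designs plus the partial-F degrees of freedom."""
    n = len(subjects)
    groups = sorted(subjects["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    gd = np.column_stack([(subjects["group"] == g).to_numpy(float) for g in groups[1:]])
    Z = _covariate_columns(subjects, covariates)
    ones = np.ones((n, 1))
    Xf = np.hstack([ones, gd, Z])
    Xr = np.hstack([ones, Z])
    df1 = len(groups) - 1
    df2 = n - Xf.shape[1]
    if df2 < 1:
        raise ValueError("more model parameters than subjects")
    return Xf, Xr, df1, df2


def _partial_f(Y: np.ndarray, Xf: np.ndarray, Xr: np.ndarray, df1: int, df2: int):
    """Column-wise partial F for the group factor; constant columns -> F=0, flagged."""
    Qf, _ = np.linalg.qr(Xf)
    Qr, _ = np.linalg.qr(Xr)
    tot = np.einsum("ij,ij->j", Y, Y)
    rss_f = tot - np.einsum("ij,ij->j", Qf.T @ Y, Qf.T @ Y)
    rss_r = tot - np.einsum("ij,ij->j", Qr.T @ Y, Qr.T @ Y)
    scale = np.maximum(tot, 1.0)
    degenerate = (rss_f < _DEGENERATE_TOL * scale) & ((rss_r - rss_f) < _DEGENERATE_TOL * scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_r - rss_f) / df1) / (rss_f / df2)
    F = np.where(degenerate, 0.0, F)
    F = np.nan_to_num(np.maximum(F, 0.0), nan=0.0, posinf=np.finfo(float).max)
    return F, degenerate


def _adjusted_group_means(Y: np.ndarray, subjects: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Covariate-adjusted group means: cell-means coding with centered covariates."""
    groups = sorted(subjects["group"].unique())
    G = np.column_stack([(subjects["group"] == g).to_numpy(float) for g in groups])
    Z = _covariate_columns(subjects, covariates)
    if Z.size:
        Z = Z - Z.mean(axis=0)
    X = np.hstack([G, Z])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return pd.DataFrame(beta[: len(groups)], index=groups)


def edge_fstats(
    matrices,
    subjects: pd.DataFrame,
    groups: list[str] | None = None,
    covariates: tuple[str, ...] = ("age", "sex"),
):
    """Per-edge partial F values and adjusted group means for a contrast.

    Returns ``(F, degenerate_flags, adjusted_means)`` where F follows the
    canonical upper-triangle edge order.
    """
    stack = as_weight_stack(matrices)
    subjects = subjects.reset_index(drop=True)
    if len(subjects) != stack.shape[0]:
        raise ValueError("subject table and matrix list must align")
    if groups is not None:
        keep = subjects["group"].isin(groups).to_numpy()
        stack, subjects = stack[keep], subjects.loc[keep].reset_index(drop=True)
    Y = vectorize_matrices(stack)
    Xf, Xr, df1, df2 = _design_matrices(subjects, list(covariates))
    F, degenerate = _partial_f(Y, Xf, Xr, df1, df2)
    means = _adjusted_group_means(Y, subjects, list(covariates))
    return F, degenerate, means


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self):
        self.parent: dict[int, int] = {}

    def find(self, a: int) -> int:
        p = self.parent
        p.setdefault(a, a)
        while p[a] != a:
            p[a] = p[p[a]]
            a = p[a]
        return a

    def union(self, a: int, b: int) -> None:
        self.parent[self.find(a)] = self.find(b)


def extract_components(fstats: np.ndarray, threshold: float, n_nodes: int) -> list[Component]:
    """Connected components of the suprathreshold-edge graph.

    Components are returned sorted by extent (descending), ties by smallest
    node id, each listing its edges in canonical order.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    iu, ju = edge_index(n_nodes)
    mask = np.asarray(fstats) >= threshold
    uf = _UnionFind()
    sup = list(zip(iu[mask].tolist(), ju[mask].tolist()))
    for i, j in sup:
        uf.union(i, j)
    buckets: dict[int, list[tuple[int, int]]] = {}
    for i, j in sup:
        buckets.setdefault(uf.find(i), []).append((i, j))
    comps = [
        Component(edges=sorted(es), nodes=sorted({n for e in es for n in e}), extent=len(es))
        for es in buckets.values()
    ]
    comps.sort(key=lambda c: (-c.extent, c.nodes[0]))
    return comps


def _max_component_extent(iu: np.ndarray, ju: np.ndarray, mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    uf = _UnionFind()
    ii, jj = iu[mask], ju[mask]
    for i, j in zip(ii.tolist(), jj.tolist()):
        uf.union(i, j)
    counts: dict[int, int] = {}
    for i in ii.tolist():
        r = uf.find(i)
        counts[r] = counts.get(r, 0) + 1
    return max(counts.values())


class NetworkBasedStatistic(BaseEstimator):
    """Estimator interface to the NBS permutation test.

    Parameters mirror :class:`NBSConfig`.  ``fit`` expects the stacked
    connectivity matrices (or a list of :class:`ConnectivityMatrix`), the
    aligned subject table, and optionally the contrast's group subset.

    Attributes (after fit)
    ----------------------
    edge_fstats_ : per-edge partial F values
    components_ : suprathreshold components with FWE-adjusted p-values
    null_max_extent_ : permutation distribution of the maximum extent
    edge_direction_ : {edge: "increase"/"decrease"} for suprathreshold edges,
        relative to the reference group (first group of the contrast).
    """

    def __init__(
        self,
        primary_threshold: float = 8.0,
        n_permutations: int = 10_000,
        covariates: tuple[str, ...] = ("age", "sex"),
        alpha: float = 0.05,
        permutation: str = "freedman-lane",
        random_state: int = 0,
    ):
        self.primary_threshold = primary_threshold
        self.n_permutations = n_permutations
        self.covariates = covariates
        self.alpha = alpha
        self.permutation = permutation
        self.random_state = random_state

    def fit(self, X, subjects: pd.DataFrame, groups: list[str] | None = None):
        cfg = NBSConfig(
            self.primary_threshold, self.n_permutations, tuple(self.covariates),
            self.alpha, self.permutation, self.random_state,
        )
        stack = as_weight_stack(X)
        subjects = subjects.reset_index(drop=True)
        if len(subjects) != stack.shape[0]:
            raise ValueError("subject table and matrices must align")
        if groups is None:
            groups = sorted(subjects["group"].unique())
        missing = [g for g in groups if g not in set(subjects["group"])]
        if missing:
            raise ValueError(f"contrast groups {missing} absent from subject table")
        keep = subjects["group"].isin(groups).to_numpy()
        stack, sub = stack[keep], subjects.loc[keep].reset_index(drop=True)
        # canonical subject order so results are invariant to input ordering
        order = np.argsort(sub["subject_id"].to_numpy(), kind="stable")
        stack, sub = stack[order], sub.iloc[order].reset_index(drop=True)

        n_nodes = stack.shape[1]
        Y = vectorize_matrices(stack)
        covs = list(cfg.covariates)
        Xf, Xr, df1, df2 = _design_matrices(sub, covs)
        F, degenerate = _partial_f(Y, Xf, Xr, df1, df2)
        comps = extract_components(F, cfg.primary_threshold, n_nodes)

        iu, ju = edge_index(n_nodes)
        rng = np.random.default_rng(cfg.seed)
        null_max = np.empty(cfg.n_permutations, dtype=int)
        if cfg.permutation == "freedman-lane":
            Qr, _ = np.linalg.qr(Xr)
            fit_r = Qr @ (Qr.T @ Y)
            resid_r = Y - fit_r
            for p in range(cfg.n_permutations):
                perm = rng.permutation(len(sub))
                Ystar = fit_r + resid_r[perm]
                Fp, _ = _partial_f(Ystar, Xf, Xr, df1, df2)
                null_max[p] = _max_component_extent(iu, ju, Fp >= cfg.primary_threshold)
        else:  # label permutation: shuffle group column, covariates stay put
            for p in range(cfg.n_permutations):
                perm = rng.permutation(len(sub))
                sub_p = sub.copy()
                sub_p["group"] = sub["group"].to_numpy()[perm]
                Xfp, Xrp, _, _ = _design_matrices(sub_p, covs)
                Fp, _ = _partial_f(Y, Xfp, Xrp, df1, df2)
                null_max[p] = _max_component_extent(iu, ju, Fp >= cfg.primary_threshold)

        for c in comps:
            c.fwe_p = float((1 + np.sum(null_max >= c.extent)) / (1 + cfg.n_permutations))

        means = _adjusted_group_means(Y, sub, covs)
        ref = groups[0]
        others = [g for g in groups if g != ref]
        direction: dict[tuple[int, int], str] = {}
        eidx = {(int(i), int(j)): k for k, (i, j) in enumerate(zip(iu, ju))}
        for c in comps:
            for e in c.edges:
                k = eidx[e]
                diff = float(np.mean([means.loc[g, k] for g in others]) - means.loc[ref, k])
                direction[e] = "increase" if diff >= 0 else "decrease"

        self.groups_ = list(groups)
        self.n_nodes_ = n_nodes
        self.edge_fstats_ = F
        self.degenerate_edges_ = degenerate
        self.adjusted_means_ = means
        self.components_ = comps
        self.null_max_extent_ = null_max
        self.edge_direction_ = direction
        return self

    def result(self) -> NBSResult:
        return NBSResult(
            groups=self.groups_,
            edge_fstats=self.edge_fstats_,
            degenerate_edges=self.degenerate_edges_,
            adjusted_means=self.adjusted_means_,
            components=self.components_,
            edge_direction=self.edge_direction_,
            null_max_extent=self.null_max_extent_,
            threshold=self.primary_threshold,
            alpha=self.alpha,
        )


def nbs_test(matrices, subjects: pd.DataFrame, groups: list[str], cfg: NBSConfig = NBSConfig()) -> NBSResult:
    """Run one NBS contrast (pairwise or omnibus) and return the result."""
    est = NetworkBasedStatistic(
        cfg.primary_threshold, cfg.n_permutations, cfg.covariates,
        cfg.alpha, cfg.permutation, cfg.seed,
    )
    est.fit(matrices, subjects, groups)
    return est.result()


def result_edge_table(result: NBSResult, atlas) -> pd.DataFrame:
    """Supplementary-table-style edge listing: labels, F, direction, component."""
    iu, ju = edge_index(_n_from_edges(len(result.edge_fstats)))
    eidx = {(int(i), int(j)): k for k, (i, j) in enumerate(zip(iu, ju))}
    rows = []
    for cid, c in enumerate(result.components):
        for e in c.edges:
            rows.append(
                dict(
                    node_i_label=atlas.labels[e[0]],
                    node_j_label=atlas.labels[e[1]],
                    F=float(result.edge_fstats[eidx[e]]),
                    direction=result.edge_direction[e],
                    component_id=cid,
                    component_fwe_p=c.fwe_p,
                )
            )
    return pd.DataFrame(rows, columns=["node_i_label", "node_j_label", "F", "direction", "component_id", "component_fwe_p"])


def _n_from_edges(n_edges: int) -> int:
    return int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
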