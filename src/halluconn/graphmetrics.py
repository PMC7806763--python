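"""Global weighted-network metrics and covariate-adjusted group comparison.

Per subject: weighted global efficiency (shortest paths on edge lengths
1/weight), weighted clustering coefficient (Onnela geometric-mean triangle
intensity), and two backbone summaries of the maximum spanning tree --
leaf fraction and hop diameter.  Group differences are tested with a linear
model per metric (metric ~ group + covariates) and the partial F for the
group factor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path
from scipy import stats

METRIC_NAMES = ("global_efficiency_w", "clustering_w", "mst_leaf_fraction", "mst_diameter", "mst_diameter_norm")


def weighted_global_efficiency(W: np.ndarray) -> float:
    """Mean over ordered node pairs of 1/d(i,j); unreachable pairs contribute 0.

    Path length uses edge lengths 1/weight, so stronger edges are shorter.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        lengths = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), 0.0)
    d = shortest_path(lengths, method="D", directed=False)
    inv = np.zeros_like(d)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & (d > 0)
    inv[off & finite] = 1.0 / d[off & finite]
    return float(inv[off].sum() / (n * (n - 1)))


def weighted_clustering(W: np.ndarray) -> float:
    """Mean Onnela clustering: C_i = sum_{jk}(w_ij w_ik w_jk)^(1/3) / (k_i(k_i-1)).

    Weights are taken as-is (expected in [0,1]); nodes with degree < 2
    contribute 0.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    A = (W > 0).astype(float)
    np.fill_diagonal(A, 0)
    cube = np.cbrt(W)
    np.fill_diagonal(cube, 0)
    tri = np.diag(cube @ cube @ cube)  # 2 x sum of triangle intensities at i
    k = A.sum(axis=1)
    C = np.zeros(n)
    ok = k >= 2
    C[ok] = tri[ok] / (k[ok] * (k[ok] - 1))
    return float(C.mean())


def maximum_spanning_tree(W: np.ndarray) -> list[tuple[int, int]]:
    """Kruskal maximum spanning tree with deterministic tie-breaking.

    Edges are scanned by (weight descending, node pair lexicographic); the
    input must describe a connected graph on its positive weights.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = W[iu, ju]
    keep = w > 0
    iu, ju, w = iu[keep], ju[keep], w[keep]
    order = np.lexsort((ju, iu, -w))
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    tree: list[tuple[int, int]] = []
    for k in order:
        ra, rb = find(int(iu[k])), find(int(ju[k]))
        if ra != rb:
            parent[ra] = rb
            tree.append((int(iu[k]), int(ju[k])))
            if len(tree) == n - 1:
                break
    if len(tree) != n - 1:
        raise ValueError("graph is disconnected: no spanning tree exists")
    return tree


def _tree_diameter(tree: list[tuple[int, int]], n: int) -> int:
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in tree:
        adj[i].append(j)
        adj[j].append(i)

    def bfs(src: int) -> tuple[int, int]:
        dist = [-1] * n
        dist[src] = 0
        stack = [src]
        far, fd = src, 0
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    if dist[v] > fd:
                        far, fd = v, dist[v]
                    stack.append(v)
        return far, fd

    a, _ = bfs(0)
    _, diam = bfs(a)  # double sweep is exact on trees
    return diam


def mst_metrics(W: np.ndarray) -> tuple[list[tuple[int, int]], float, int]:
    """Maximum spanning tree plus (leaf_fraction, hop diameter)."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    tree = maximum_spanning_tree(W)
    deg = np.zeros(n, dtype=int)
    for i, j in tree:
        deg[i] += 1
        deg[j] += 1
    leaf_fraction = float((deg == 1).sum() / (n - 1))
    return tree, leaf_fraction, _tree_diameter(tree, n)


def global_metrics_table(matrices, subject_ids=None) -> pd.DataFrame:
    """Per-subject table of all global metrics (one row per subject)."""
    from .connectome import as_weight_stack

    stack = as_weight_stack(matrices)
    if subject_ids is None:
        subject_ids = [getattr(m, "subject_id", str(i)) for i, m in enumerate(matrices)] \
            if not isinstance(matrices, np.ndarray) else [str(i) for i in range(len(stack))]
    rows = []
    for sid, W in zip(subject_ids, stack):
        tree, lf, diam = mst_metrics(W)
        rows.append(
            dict(
                subject_id=sid,
                global_efficiency_w=weighted_global_efficiency(W),
                clustering_w=weighted_clustering(W),
                mst_leaf_fraction=lf,
                mst_diameter=diam,
                mst_diameter_norm=diam / (W.shape[0] - 1),
            )
        )
    return pd.DataFrame(rows)


def compare_global_metrics(
    metrics: pd.DataFrame,
    subjects: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> pd.DataFrame:
    """Omnibus group test per metric: partial F for the group factor in
    metric ~ group + covariates.

    Returns a table with columns metric, F, df1, df2, p.
    """
    from .nbs import _design_matrices, _partial_f

    merged = metrics.merge(subjects, on="subject_id", how="inner")
    counts = merged.groupby("group").size()
    if (counts < 3).any() or len(counts) < 2:
        raise ValueError("need >= 2 groups with >= 3 subjects each")
    Xf, Xr, df1, df2 = _design_matrices(merged, list(covariates))
    rows = []
    for name in [c for c in METRIC_NAMES if c in metrics.columns]:
        y = merged[name].to_numpy(dtype=float)[:, None]
        F, _ = _partial_f(y, Xf, Xr, df1, df2)
        rows.append(dict(metric=name, F=float(F[0]), df1=df1, df2=df2,
                         p=float(stats.f.sf(F[0], df1, df2))))
    return pd.DataFrame(rows)
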