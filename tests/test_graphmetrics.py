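import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import random_symmetric
from halluconn.graphmetrics import (compare_global_metrics,
                                    maximum_spanning_tree, mst_metrics,
                                    weighted_clustering,
                                    weighted_global_efficiency)


def brute_force_efficiency(W):
    """All-pairs shortest paths by exhaustive simple-path enumeration."""
    n = W.shape[0]
    total = 0.0
    for i, j in itertools.permutations(range(n), 2):
        best = np.inf
        for k in range(n - 1):
            for mid in itertools.permutations([m for m in range(n) if m not in (i, j)], k):
                path = (i, *mid, j)
                if all(W[a, b] > 0 for a, b in zip(path, path[1:])):
                    best = min(best, sum(1.0 / W[a, b] for a, b in zip(path, path[1:])))
        if np.isfinite(best):
            total += 1.0 / best
    return total / (n * (n - 1))


def brute_force_clustering(W):
    n = W.shape[0]
    vals = []
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        s = 0.0
        for j in nbrs:
            for l in nbrs:
                if j != l and W[j, l] > 0:
                    s += (W[i, j] * W[i, l] * W[j, l]) ** (1 / 3)
        vals.append(s / (k * (k - 1)))
    return float(np.mean(vals))


class TestEfficiency:
    def test_complete_unit_graph(self):
        W = 1.0 - np.eye(4)
        assert weighted_global_efficiency(W) == pytest.approx(1.0)

    def test_isolated_nodes(self):
        assert weighted_global_efficiency(np.zeros((2, 2))) == 0.0

    def test_matches_bruteforce_on_random_graph(self):
        rng = np.random.default_rng(5)
        W = random_symmetric(6, rng, density=0.7)
        assert weighted_global_efficiency(W) == pytest.approx(brute_force_efficiency(W), abs=1e-12)

    def test_adding_edge_never_decreases(self):
        rng = np.random.default_rng(6)
        W = random_symmetric(6, rng, density=0.5)
        before = weighted_global_efficiency(W)
        W2 = W.copy()
        zeros = np.argwhere((W2 == 0) & ~np.eye(6, dtype=bool))
        i, j = zeros[0]
        W2[i, j] = W2[j, i] = 0.5
        assert weighted_global_efficiency(W2) >= before - 1e-12


class TestClustering:
    def test_unit_triangle(self):
        W = 1.0 - np.eye(3)
        assert weighted_clustering(W) == pytest.approx(1.0)

    def test_star_has_no_triangles(self):
        W = np.zeros((5, 5))
        W[0, 1:] = W[1:, 0] = 0.8
        assert weighted_clustering(W) == 0.0

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(7)
        W = random_symmetric(5, rng, density=0.8)
        assert weighted_clustering(W) == pytest.approx(brute_force_clustering(W), abs=1e-12)


class TestMST:
    def test_path_topology(self):
        W = np.zeros((5, 5))
        for i in range(4):
            W[i, i + 1] = W[i + 1, i] = 0.9  # strong chain
        W[0, 2] = W[2, 0] = 0.1
        tree, leaf_fraction, diameter = mst_metrics(W)
        assert leaf_fraction == pytest.approx(0.5)
        assert diameter == 4

    def test_star_topology(self):
        W = np.zeros((5, 5))
        W[0, 1:] = W[1:, 0] = 0.9
        for i, j in itertools.combinations(range(1, 5), 2):
            W[i, j] = W[j, i] = 0.1
        tree, leaf_fraction, diameter = mst_metrics(W)
        assert leaf_fraction == 1.0
        assert diameter == 2

    def test_maximum_weight_by_enumeration(self):
        rng = np.random.default_rng(8)
        W = random_symmetric(6, rng)
        tree = maximum_spanning_tree(W)
        got = sum(W[i, j] for i, j in tree)
        edges = list(itertools.combinations(range(6), 2))
        best = 0.0
        for cand in itertools.combinations(edges, 5):
            parent = list(range(6))

            def find(a):
                while parent[a] != a:
                    a = parent[a]
                return a

            ok = True
            for i, j in cand:
                ri, rj = find(i), find(j)
                if ri == rj:
                    ok = False
                    break
                parent[ri] = rj
            if ok:
                best = max(best, sum(W[i, j] for i, j in cand))
        assert got == pytest.approx(best, abs=1e-12)

    def test_tree_edge_removal_disconnects(self):
        rng = np.random.default_rng(9)
        W = random_symmetric(7, rng)
        tree, *_ = mst_metrics(W)
        assert len(tree) == 6
        for drop in range(len(tree)):
            sub = [e for k, e in enumerate(tree) if k != drop]
            Wt = np.zeros_like(W)
            for i, j in sub:
                Wt[i, j] = Wt[j, i] = 1.0
            with pytest.raises(ValueError):
                maximum_spanning_tree(Wt)

    def test_disconnected_input_rejected(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        with pytest.raises(ValueError):
            maximum_spanning_tree(W)


def test_relabeling_invariance():
    rng = np.random.default_rng(10)
    W = random_symmetric(7, rng, density=0.8)
    perm = rng.permutation(7)
    Wp = W[perm][:, perm]
    assert weighted_global_efficiency(W) == pytest.approx(weighted_global_efficiency(Wp))
    assert weighted_clustering(W) == pytest.approx(weighted_clustering(Wp))
    _, lf, d = mst_metrics(W)
    _, lfp, dp = mst_metrics(Wp)
    assert (lf, d) == (lfp, dp)


def _toy_metrics(groups, effect=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, n in groups.items():
        for k in range(n):
            shift = effect if g != "HC" else 0.0
            rows.append(dict(subject_id=f"{g}{k}", group=g,
                             age=rng.normal(40, 12), sex=rng.choice(["m", "f"]),
                             global_efficiency_w=rng.normal(0.5 + shift * 0.1, 0.1)))
    df = pd.DataFrame(rows)
    metrics = df[["subject_id", "global_efficiency_w"]]
    subjects = df[["subject_id", "group", "age", "sex"]]
    return metrics, subjects


class TestGroupComparison:
    def test_null_pvalues_roughly_uniform(self):
        ps = []
        for rep in range(40):
            metrics, subjects = _toy_metrics({"HC": 15, "BD": 15}, effect=0.0, seed=rep)
            res = compare_global_metrics(metrics, subjects)
            ps.append(res["p"].iloc[0])
        # Kolmogorov-Smirnov against U(0,1) at a lenient level
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_power_at_one_sd_effect(self):
        hits = 0
        for rep in range(50):
            metrics, subjects = _toy_metrics({"HC": 30, "BD": 30}, effect=1.0, seed=100 + rep)
            res = compare_global_metrics(metrics, subjects)
            hits += res["p"].iloc[0] < 0.05
        assert hits >= 40  # >= 80% of replicates

    def test_partial_f_matches_normal_equations(self):
        metrics, subjects = _toy_metrics({"HC": 5, "BD": 5}, effect=0.6, seed=1)
        res = compare_global_metrics(metrics, subjects, covariates=("age",))
        # normal-equations oracle for the same partial F
        y = metrics["global_efficiency_w"].to_numpy()
        g = (subjects["group"] == "BD").to_numpy(float)
        a = subjects["age"].to_numpy()
        Xf = np.column_stack([np.ones(10), g, a])
        Xr = np.column_stack([np.ones(10), a])

        def rss(X):
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            r = y - X @ beta
            return r @ r

        F = (rss(Xr) - rss(Xf)) / 1 / (rss(Xf) / (10 - 3))
        assert res["F"].iloc[0] == pytest.approx(F, abs=1e-10)
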