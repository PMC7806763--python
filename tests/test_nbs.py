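import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from halluconn._edges import edge_index, unvectorize
from halluconn.nbs import (NBSConfig, NetworkBasedStatistic, edge_fstats,
                           extract_components, nbs_test)


def _toy_subjects(groups, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, n in groups.items():
        for k in range(n):
            rows.append(dict(subject_id=f"{g}{k:02d}", group=g,
                             age=float(rng.normal(40, 10)), sex=rng.choice(["m", "f"])))
    return pd.DataFrame(rows)


def _toy_matrices(subjects, n_nodes, seed=0, bump_edges=(), bump_group=None, bump=0.0):
    rng = np.random.default_rng(seed)
    n_sub = len(subjects)
    iu, ju = edge_index(n_nodes)
    Y = rng.uniform(0.2, 0.6, size=(n_sub, len(iu)))
    if bump_edges:
        eidx = {(i, j): k for k, (i, j) in enumerate(zip(iu, ju))}
        mask = (subjects["group"] == bump_group).to_numpy()
        for e in bump_edges:
            Y[mask, eidx[e]] += bump
    return np.stack([unvectorize(y, n_nodes) for y in Y])


class TestEdgeFStats:
    def test_two_group_f_equals_t_squared(self):
        subjects = _toy_subjects({"HC": 8, "BD": 7})
        W = _toy_matrices(subjects, 4, seed=1)
        F, _, _ = edge_fstats(W, subjects, covariates=())
        iu, ju = edge_index(4)
        hc = (subjects["group"] == "HC").to_numpy()
        for k in range(len(iu)):
            y = W[:, iu[k], ju[k]]
            t, _ = stats.ttest_ind(y[~hc], y[hc], equal_var=True)
            assert F[k] == pytest.approx(t**2, abs=1e-10)

    def test_constant_edge_flagged_zero(self):
        subjects = _toy_subjects({"HC": 5, "BD": 5})
        W = _toy_matrices(subjects, 3, seed=2)
        W[:, 0, 1] = W[:, 1, 0] = 0.42
        F, degenerate, _ = edge_fstats(W, subjects, covariates=())
        assert F[0] == 0.0
        assert degenerate[0]
        assert not degenerate[1:].any()

    def test_three_group_f_matches_normal_equations(self):
        subjects = _toy_subjects({"HC": 6, "BD": 5, "SCZ-H": 7}, seed=3)
        W = _toy_matrices(subjects, 3, seed=4)
        F, _, _ = edge_fstats(W, subjects, covariates=("age",))
        y = W[:, 0, 1]
        n = len(subjects)
        d1 = (subjects["group"] == "HC").to_numpy(float)
        d2 = (subjects["group"] == "SCZ-H").to_numpy(float)
        a = subjects["age"].to_numpy()
        Xf = np.column_stack([np.ones(n), d1, d2, a])
        Xr = np.column_stack([np.ones(n), a])

        def rss(X):
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            r = y - X @ beta
            return float(r @ r)

        expected = ((rss(Xr) - rss(Xf)) / 2) / (rss(Xf) / (n - 4))
        assert F[0] == pytest.approx(expected, abs=1e-10)

    def test_adjusted_means_without_covariates_are_plain_means(self):
        subjects = _toy_subjects({"HC": 6, "BD": 6})
        W = _toy_matrices(subjects, 3, seed=5)
        _, _, means = edge_fstats(W, subjects, covariates=())
        hc = (subjects["group"] == "HC").to_numpy()
        assert means.loc["HC", 0] == pytest.approx(W[hc, 0, 1].mean(), abs=1e-10)


class TestComponents:
    def test_chain_is_one_component(self):
        iu, ju = edge_index(5)
        f = np.zeros(len(iu))
        for e in [(1, 2), (2, 3)]:
            f[[k for k, (i, j) in enumerate(zip(iu, ju)) if (i, j) == e][0]] = 9.0
        comps = extract_components(f, 8.0, 5)
        assert len(comps) == 1
        assert comps[0].extent == 2
        assert comps[0].nodes == [1, 2, 3]

    def test_disjoint_edges_are_two_components(self):
        iu, ju = edge_index(5)
        f = np.zeros(len(iu))
        for e in [(0, 1), (3, 4)]:
            f[[k for k, (i, j) in enumerate(zip(iu, ju)) if (i, j) == e][0]] = 9.0
        comps = extract_components(f, 8.0, 5)
        assert [c.extent for c in comps] == [1, 1]

    def test_matches_networkx_partition(self):
        rng = np.random.default_rng(6)
        iu, ju = edge_index(20)
        f = np.where(rng.random(len(iu)) < 0.08, 10.0, 1.0)
        comps = extract_components(f, 8.0, 20)
        g = nx.Graph()
        g.add_edges_from(zip(iu[f >= 8.0], ju[f >= 8.0]))
        expected = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
        got = sorted((c.nodes for c in comps), key=lambda c: c[0])
        assert [list(map(int, c)) for c in got] == [list(map(int, c)) for c in expected]

    def test_raising_threshold_shrinks_components(self):
        rng = np.random.default_rng(7)
        f = rng.uniform(0, 20, size=len(edge_index(12)[0]))
        lo = extract_components(f, 6.0, 12)
        hi = extract_components(f, 10.0, 12)
        max_lo = lo[0].extent if lo else 0
        max_hi = hi[0].extent if hi else 0
        assert max_hi <= max_lo


class TestPermutationTest:
    def test_minimum_attainable_p(self):
        subjects = _toy_subjects({"HC": 15, "BD": 15}, seed=8)
        W = _toy_matrices(subjects, 6, seed=9,
                          bump_edges=[(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)],
                          bump_group="BD", bump=0.8)
        # high threshold: only near-perfect label alignment crosses it,
        # so the overwhelming observed component attains the lower bound
        res = nbs_test(W, subjects, ["HC", "BD"],
                       NBSConfig(primary_threshold=100.0, n_permutations=500,
                                 covariates=(), seed=1))
        assert res.components
        assert res.components[0].fwe_p == pytest.approx(1 / 501)
        assert all(c.fwe_p >= 1 / 501 for c in res.components)

    def test_direction_labels(self):
        subjects = _toy_subjects({"HC": 12, "BD": 12}, seed=10)
        W = _toy_matrices(subjects, 6, seed=11, bump_edges=[(0, 1), (1, 2)],
                          bump_group="BD", bump=0.5)
        res = nbs_test(W, subjects, ["HC", "BD"],
                       NBSConfig(n_permutations=200, covariates=(), seed=2))
        for e in res.components[0].edges:
            if e in [(0, 1), (1, 2)]:
                assert res.edge_direction[e] == "increase"

    def test_subject_order_invariance(self):
        subjects = _toy_subjects({"HC": 10, "BD": 10}, seed=12)
        W = _toy_matrices(subjects, 5, seed=13, bump_edges=[(0, 1)], bump_group="BD", bump=0.4)
        cfg = NBSConfig(n_permutations=200, covariates=("age",), seed=3)
        res1 = nbs_test(W, subjects, ["HC", "BD"], cfg)
        perm = np.random.default_rng(0).permutation(len(subjects))
        res2 = nbs_test(W[perm], subjects.iloc[perm], ["HC", "BD"], cfg)
        np.testing.assert_allclose(res1.edge_fstats, res2.edge_fstats, atol=1e-10)
        assert [c.extent for c in res1.components] == [c.extent for c in res2.components]
        assert [c.fwe_p for c in res1.components] == [c.fwe_p for c in res2.components]

    def test_fwe_p_bounds_and_monotonicity(self):
        subjects = _toy_subjects({"HC": 10, "BD": 10}, seed=14)
        W = _toy_matrices(subjects, 6, seed=15, bump_edges=[(0, 1), (1, 2), (3, 4)],
                          bump_group="BD", bump=0.45)
        res = nbs_test(W, subjects, ["HC", "BD"],
                       NBSConfig(n_permutations=300, covariates=(), seed=4))
        ps = [c.fwe_p for c in res.components]
        extents = [c.extent for c in res.components]
        for p in ps:
            assert 1 / 301 <= p <= 1.0
        for (e1, p1), (e2, p2) in zip(zip(extents, ps), zip(extents[1:], ps[1:])):
            if e1 >= e2:
                assert p1 <= p2

    def test_label_permutation_option(self):
        subjects = _toy_subjects({"HC": 10, "BD": 10}, seed=16)
        W = _toy_matrices(subjects, 5, seed=17, bump_edges=[(0, 1), (1, 2)],
                          bump_group="BD", bump=0.5)
        res = nbs_test(W, subjects, ["HC", "BD"],
                       NBSConfig(n_permutations=200, covariates=("age",),
                                 permutation="labels", seed=5))
        assert res.components[0].fwe_p < 0.05

    def test_invalid_contrast_rejected(self):
        subjects = _toy_subjects({"HC": 10, "BD": 10})
        W = _toy_matrices(subjects, 4)
        with pytest.raises(ValueError):
            nbs_test(W, subjects, ["HC", "SCZ-H"], NBSConfig(n_permutations=100, covariates=()))
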