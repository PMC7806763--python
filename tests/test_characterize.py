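import numpy as np
import pandas as pd
import pytest
from scipy import stats

from halluconn.characterize import (conjunction, degree_ranking,
                                    demographics_summary, group_percentage,
                                    lobe_proportions, spearman_fdr)


class TestLobeProportions:
    def test_single_cross_lobe_edge(self, aal90):
        frontal = aal90.nodes_in_lobe("frontal")[0]
        temporal = aal90.nodes_in_lobe("temporal")[0]
        mat = lobe_proportions([(frontal, temporal)], aal90)
        assert mat.loc["frontal", "temporal"] == 1.0
        assert mat.loc["temporal", "frontal"] == 1.0
        assert mat.loc["frontal", "frontal"] == 0.0

    def test_two_edges_split(self, aal90):
        f = aal90.nodes_in_lobe("frontal")[:1][0]
        t1, t2, t3 = aal90.nodes_in_lobe("temporal")[:3]
        mat = lobe_proportions([(f, t1), (t2, t3)], aal90)
        assert mat.loc["frontal", "temporal"] == 0.5
        assert mat.loc["temporal", "temporal"] == 0.5

    def test_random_component_sums_to_one(self, aal90):
        rng = np.random.default_rng(3)
        edges = [tuple(sorted(rng.choice(90, 2, replace=False))) for _ in range(25)]
        edges = list(set(edges))
        mat = lobe_proportions(edges, aal90)
        # unordered-pair total: upper triangle including diagonal
        total = sum(mat.iloc[i, j] for i in range(6) for j in range(i, 6))
        assert total == pytest.approx(1.0)
        # hand count one cell
        lobes = aal90.lobes
        ft = sum(1 for i, j in edges if sorted((lobes[i], lobes[j])) == ["frontal", "temporal"])
        assert mat.loc["frontal", "temporal"] == pytest.approx(ft / len(edges))

    def test_empty_component_rejected(self, aal90):
        with pytest.raises(ValueError):
            lobe_proportions([], aal90)


class TestDegreeRanking:
    def test_star_center_ranks_first(self, atlas10):
        edges = [(0, i) for i in range(1, 5)]
        rank = degree_ranking(edges, atlas10)
        assert rank.iloc[0]["degree"] == 4
        assert rank.iloc[0]["label"] == atlas10.labels[0]

    def test_path_degrees(self, atlas10):
        rank = degree_ranking([(0, 1), (1, 2), (2, 3)], atlas10)
        by_label = dict(zip(rank["label"], rank["degree"]))
        assert by_label[atlas10.labels[1]] == 2
        assert by_label[atlas10.labels[0]] == 1

    def test_handshake_lemma(self, atlas10):
        rng = np.random.default_rng(4)
        edges = list({tuple(sorted(rng.choice(10, 2, replace=False))) for _ in range(12)})
        rank = degree_ranking(edges, atlas10)
        assert rank["degree"].sum() == 2 * len(edges)
        assert (rank["degree"] >= 1).all()
        assert (rank["degree"].diff().dropna() <= 0).all()


class TestConjunction:
    def test_overlap(self):
        assert conjunction([(1, 2), (2, 3)], [(3, 2), (4, 5)]) == {(2, 3)}

    def test_disjoint(self):
        assert conjunction([(1, 2)], [(3, 4)]) == set()

    def test_idempotent(self):
        a = [(1, 2), (5, 7)]
        assert conjunction(a, a) == {(1, 2), (5, 7)}


class TestSpearmanFDR:
    def test_perfect_monotone(self):
        vals = pd.DataFrame({"m": [1, 2, 3, 4, 5]})
        out = spearman_fdr(vals, pd.Series([2.0, 4.1, 4.2, 8.0, 9.0]))
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_ties_match_rank_then_pearson(self):
        x = pd.Series([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 8.0])
        y = pd.Series([3.0, 1.0, 4.0, 4.0, 6.0, 2.0, 7.0, 9.0])
        out = spearman_fdr(pd.DataFrame({"m": x}), y)
        rho_oracle = stats.pearsonr(stats.rankdata(x), stats.rankdata(y)).statistic
        assert out["rho"].iloc[0] == pytest.approx(rho_oracle, abs=1e-12)

    def test_bh_fixed_point_and_monotonicity(self):
        rng = np.random.default_rng(5)
        vals = pd.DataFrame({f"m{k}": rng.normal(size=20) for k in range(6)})
        scores = pd.Series(rng.normal(size=20))
        out = spearman_fdr(vals, scores)
        assert (out["p_fdr"] >= out["p"] - 1e-15).all()
        srt = out.sort_values("p")
        assert (srt["p_fdr"].diff().dropna() >= -1e-15).all()

    def test_missing_scores_dropped_pairwise(self):
        vals = pd.DataFrame({"m": np.arange(8.0)})
        scores = pd.Series([1.0, 2, 3, np.nan, 5, 6, 7, 8])
        out = spearman_fdr(vals, scores)
        assert out["n"].iloc[0] == 7

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman_fdr(pd.DataFrame({"m": [1.0, 2, 3]}), pd.Series([1.0, 2, 3]))


def _sex_table(counts):
    rows = []
    for g, (m, f) in counts.items():
        rows += [dict(subject_id=f"{g}{i}", group=g, sex="m", age=40.0,
                      motion=0.1, has_auditory=True, has_visual=False) for i in range(m)]
        rows += [dict(subject_id=f"{g}m{i}", group=g, sex="f", age=40.0,
                      motion=0.1, has_auditory=False, has_visual=True) for i in range(f)]
    return pd.DataFrame(rows)


class TestDemographics:
    def test_sex_chi_square_on_reference_counts(self):
        """Male/female counts of the five-group cohort give chi2(4) = 21.5."""
        table = _sex_table({"SCZ-H": (67, 32), "BD-H": (37, 37), "BD": (23, 19),
                            "NC-H": (10, 30), "HC": (121, 107)})
        out = demographics_summary(table, continuous=(), dichotomous=("sex",))
        sex = out["variables"]["sex"]
        assert sex["chi2"] == pytest.approx(21.5, abs=0.05)
        assert sex["df"] == 4
        assert sex["p"] < 0.001

    def test_percentages_use_group_denominator(self):
        assert group_percentage(33, 40) == pytest.approx(82.5)
        assert group_percentage(51, 74) == pytest.approx(68.9, abs=0.05)
        assert group_percentage(80, 99) == pytest.approx(80.8, abs=0.05)

    def test_identical_groups_give_zero_chi_square(self):
        table = _sex_table({"HC": (10, 5), "BD": (10, 5)})
        out = demographics_summary(table, continuous=(), dichotomous=("sex",))
        assert out["variables"]["sex"]["chi2"] == pytest.approx(0.0, abs=1e-12)

    def test_single_level_variable_rejected(self):
        table = _sex_table({"HC": (5, 0), "BD": (5, 0)})
        with pytest.raises(ValueError):
            demographics_summary(table, continuous=(), dichotomous=("sex",))

    def test_continuous_anova(self):
        rng = np.random.default_rng(6)
        table = _sex_table({"HC": (10, 10), "BD": (10, 10)})
        table["age"] = rng.normal(40, 10, size=len(table))
        out = demographics_summary(table, continuous=("age",), dichotomous=("sex",))
        g1 = table.loc[table["group"] == "HC", "age"]
        g2 = table.loc[table["group"] == "BD", "age"]
        F, p = stats.f_oneway(g1, g2)
        assert out["variables"]["age"]["F"] == pytest.approx(F)
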