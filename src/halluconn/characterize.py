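"""Characterization of NBS components and cohort tables.

Covers four descriptive analyses: lobe-pair proportions of altered edges,
node-degree ranking within a component, conjunction (edge-set intersection)
across contrasts, Spearman symptom correlations with Benjamini-Hochberg FDR,
and a demographics summary table with one-way ANOVA / Pearson chi-square
omnibus tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atlas import LOBES, Atlas
from ._edges import canonical_edge


def lobe_proportions(component_edges, atlas: Atlas) -> pd.DataFrame:
    """Proportion of altered edges between each (unordered) lobe pair.

    The count of altered edges joining lobes (a, b) is divided by the total
    number of altered edges, so entries over unordered pairs (within-lobe
    included) sum to 1.  Returned as a symmetric lobe x lobe DataFrame.
    """
    edges = [canonical_edge(*e) for e in component_edges]
    if not edges:
        raise ValueError("empty component")
    lobes = atlas.lobes
    mat = pd.DataFrame(0.0, index=list(LOBES), columns=list(LOBES))
    for i, j in edges:
        a, b = sorted((lobes[i], lobes[j]))
        mat.loc[a, b] += 1
        if a != b:
            mat.loc[b, a] += 1
    return mat / len(edges)


def degree_ranking(component_edges, atlas: Atlas) -> pd.DataFrame:
    """Node degree within a component, ranked descending (ties by label)."""
    edges = [canonical_edge(*e) for e in component_edges]
    if not edges:
        raise ValueError("empty component")
    deg: dict[int, int] = {}
    for i, j in edges:
        deg[i] = deg.get(i, 0) + 1
        deg[j] = deg.get(j, 0) + 1
    rows = [dict(label=atlas.labels[n], degree=d) for n, d in deg.items()]
    return (
        pd.DataFrame(rows)
        .sort_values(["degree", "label"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )


def conjunction(*components) -> set[tuple[int, int]]:
    """Exact intersection of edge sets (unordered node pairs)."""
    if len(components) < 2:
        raise ValueError("conjunction needs at least 2 components")
    sets = [{canonical_edge(*e) for e in comp} for comp in components]
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


def spearman_fdr(values: pd.DataFrame, scores: pd.Series, alpha: float = 0.05) -> pd.DataFrame:
    """Spearman correlation of each column of ``values`` with symptom scores.

    Missing scores are dropped pairwise; the Benjamini-Hochberg procedure is
    applied across the tested family.  Returns columns variable, n, rho,
    p, p_fdr, significant.
    """
    scores = pd.Series(scores).astype(float)
    rows = []
    for col in values.columns:
        v = pd.to_numeric(values[col], errors="coerce")
        ok = v.notna() & scores.notna()
        n = int(ok.sum())
        if n < 4:
            raise ValueError(f"fewer than 4 paired observations for {col!r}")
        rho, p = stats.spearmanr(v[ok], scores[ok])
        rows.append(dict(variable=col, n=n, rho=float(rho), p=float(p)))
    out = pd.DataFrame(rows)
    rej, p_adj, *_ = multipletests(out["p"], alpha=alpha, method="fdr_bh")
    out["p_fdr"] = p_adj
    out["significant"] = rej
    return out


_CONTINUOUS = ("age", "motion")
_DICHOTOMOUS = ("sex", "has_auditory", "has_visual")


def demographics_summary(
    subjects: pd.DataFrame,
    continuous: tuple[str, ...] = _CONTINUOUS,
    dichotomous: tuple[str, ...] = _DICHOTOMOUS,
    dropna_chisq: bool = False,
) -> dict:
    """Cohort-characteristics summary with omnibus tests.

    Continuous variables get per-group mean (SD) and a one-way ANOVA F;
    dichotomous variables get per-group counts/percentages (denominator =
    full group n) and a Pearson chi-square without continuity correction,
    df = (groups-1) x (levels-1).  Variables constant across the cohort
    raise, since the chi-square is undefined on a single observed level.
    """
    groups = sorted(subjects["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out: dict = {"groups": {g: int((subjects["group"] == g).sum()) for g in groups}, "variables": {}}
    for var in continuous:
        per = {
            g: dict(
                mean=float(subjects.loc[subjects["group"] == g, var].mean()),
                sd=float(subjects.loc[subjects["group"] == g, var].std()),
            )
            for g in groups
        }
        samples = [subjects.loc[subjects["group"] == g, var].dropna() for g in groups]
        F, p = stats.f_oneway(*samples)
        out["variables"][var] = dict(kind="continuous", per_group=per, test="anova",
                                     F=float(F), df=(len(groups) - 1), p=float(p))
    for var in dichotomous:
        v = subjects[var]
        if dropna_chisq:
            mask = v.notna()
        else:
            mask = pd.Series(True, index=subjects.index)
        tab = pd.crosstab(subjects.loc[mask, "group"], v[mask])
        if tab.shape[1] < 2:
            raise ValueError(f"variable {var!r} has a single observed level")
        chi2, p, dof, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
        per = {}
        for g in groups:
            gmask = subjects["group"] == g
            n_g = int(gmask.sum())
            pos = subjects.loc[gmask, var]
            pos_count = int((pos == "m").sum()) if var == "sex" else int((pos == True).sum())  # noqa: E712
            per[g] = dict(count=pos_count, percent=100.0 * pos_count / n_g if n_g else np.nan)
        out["variables"][var] = dict(kind="dichotomous", per_group=per, test="chi2",
                                     chi2=float(chi2), df=int(dof), p=float(p))
    return out


def group_percentage(count: int, total: int) -> float:
    """Printed-table percentage: 100 * count / group n."""
    if total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * count / total
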