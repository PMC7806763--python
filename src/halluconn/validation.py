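"""Simulation studies validating the pipeline under known ground truth.

Three studies cover the statistical guarantees a practitioner cares about:

* **Null calibration** — with no planted effects, group labels are
  exchangeable and the NBS family-wise error rate at alpha = 0.05 should
  not exceed its nominal level (within simulation error).
* **Planted-component recovery** — a connected component of coherence
  increase should be detected and its edges recovered.
* **Concordant/inverted recovery** — two hallucination groups share one
  dysconnected edge set while a third carries an inverted pattern on an
  adjoining set; the omnibus contrast must flag the joint component and
  k-means on edge profiles must separate the two behaviors.

All studies run at reduced desk scale (30 nodes, 256 timepoints, 500
permutations) and are deterministic given the base seed.
"""

from __future__ import annotations

import numpy as np

from .atlas import generate_atlas
from .cohort import PlantedEffect, generate_cohort, generate_timeseries
from .connectome import as_weight_stack, build_connectomes
from .edgecluster import EdgeKMeans, edge_profiles
from .nbs import NBSConfig, nbs_test


def _seeds(base: int, n: int) -> list[int]:
    children = np.random.SeedSequence(base).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def nbs_null_calibration(
    n_replicates: int = 200,
    n_per_group: int = 15,
    n_nodes: int = 30,
    n_permutations: int = 500,
    timepoints: int = 256,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Family-wise false-positive rate of the NBS over null synthetic cohorts.

    Each replicate simulates a two-group cohort with *no* planted effects,
    builds connectomes, runs the covariate-adjusted NBS and records whether
    any component reaches FWE p < alpha.
    """
    atlas = generate_atlas(n_nodes, "custom", seed=seed)
    hits = 0
    for rep, s in enumerate(_seeds(seed, n_replicates)):
        subjects = generate_cohort({"HC": n_per_group, "SCZ-H": n_per_group}, seed=s)
        ts = generate_timeseries(subjects, atlas, [], timepoints=timepoints, seed=s + 1)
        W = as_weight_stack(build_connectomes(ts))
        res = nbs_test(W, subjects, ["HC", "SCZ-H"],
                       NBSConfig(n_permutations=n_permutations, seed=s + 2))
        hits += any(c.fwe_p < alpha for c in res.components)
    return dict(false_positive_rate=hits / n_replicates, n_replicates=n_replicates,
                alpha=alpha, n_per_group=n_per_group, n_nodes=n_nodes)


def nbs_planted_recovery(
    n_replicates: int = 25,
    n_per_group: int = 25,
    shared_variance: float = 0.5,
    n_component_edges: int = 10,
    n_nodes: int = 30,
    n_permutations: int = 500,
    timepoints: int = 256,
    seed: int = 0,
) -> dict:
    """Edge sensitivity for a planted connected component of increase.

    The planted component is a path of ``n_component_edges`` edges; per
    replicate the fraction of planted edges inside significant components
    (edge sensitivity) is recorded.
    """
    atlas = generate_atlas(n_nodes, "custom", seed=seed)
    edges = tuple((i, i + 1) for i in range(n_component_edges))
    sensitivities = []
    detected = 0
    for rep, s in enumerate(_seeds(seed + 1, n_replicates)):
        subjects = generate_cohort({"HC": n_per_group, "SCZ-H": n_per_group}, seed=s)
        eff = PlantedEffect("SCZ-H", edges, "increase", shared_variance)
        ts = generate_timeseries(subjects, atlas, [eff], timepoints=timepoints, seed=s + 1)
        W = as_weight_stack(build_connectomes(ts))
        res = nbs_test(W, subjects, ["HC", "SCZ-H"],
                       NBSConfig(n_permutations=n_permutations, seed=s + 2))
        recovered = {e for c in res.significant_components for e in c.edges}
        detected += bool(res.significant_components)
        sensitivities.append(len(recovered & set(edges)) / len(edges))
    sens = np.asarray(sensitivities)
    return dict(
        mean_edge_sensitivity=float(sens.mean()),
        fraction_above_70pct=float((sens >= 0.70).mean()),
        detection_rate=detected / n_replicates,
        n_replicates=n_replicates,
    )


def concordant_inverted_recovery(
    n_replicates: int = 20,
    n_per_group: int = 20,
    shared_variance: float = 0.35,
    n_nodes: int = 30,
    n_permutations: int = 500,
    timepoints: int = 256,
    seed: int = 0,
) -> dict:
    """Omnibus detection plus k-means separation of opposed edge behaviors.

    Edge set A (a 5-edge path) gains coherence in both NC-H and SCZ-H;
    edge set B (an adjoining 5-edge path sharing one node, so A and B form
    one connected component) gains coherence only in BD-H.  Per replicate,
    the omnibus three-group NBS is run; if its largest significant component
    recovers planted edges from both sets, the component's edge profiles are
    clustered with k = 2 and the agreement between the clustering and the
    planted A/B split recorded (max over the two label assignments).
    """
    atlas = generate_atlas(n_nodes, "custom", seed=seed)
    set_a = tuple((i, i + 1) for i in range(5))
    set_b = tuple((i, i + 1) for i in range(5, 10))
    agreements = []
    significant = 0
    for rep, s in enumerate(_seeds(seed + 2, n_replicates)):
        subjects = generate_cohort(
            {"HC": n_per_group, "NC-H": n_per_group, "SCZ-H": n_per_group, "BD-H": n_per_group},
            seed=s)
        effects = [
            PlantedEffect("NC-H", set_a, "increase", shared_variance),
            PlantedEffect("SCZ-H", set_a, "increase", shared_variance),
            PlantedEffect("BD-H", set_b, "increase", shared_variance),
        ]
        ts = generate_timeseries(subjects, atlas, effects, timepoints=timepoints, seed=s + 1)
        W = as_weight_stack(build_connectomes(ts))
        groups = ["NC-H", "SCZ-H", "BD-H"]
        res = nbs_test(W, subjects, groups, NBSConfig(n_permutations=n_permutations, seed=s + 2))
        if not res.significant_components:
            agreements.append(np.nan)
            continue
        significant += 1
        comp = res.significant_components[0]
        in_a = [e for e in comp.edges if e in set_a]
        in_b = [e for e in comp.edges if e in set_b]
        if not in_a or not in_b:
            agreements.append(np.nan)
            continue
        prof = edge_profiles(comp.edges, W, subjects, groups)
        labels = dict(zip(
            [tuple(map(int, e.split("--"))) for e in prof.index],
            EdgeKMeans(k=2, random_state=s % 2**31).fit_predict(prof),
        ))
        got = np.array([labels[e] for e in in_a] + [labels[e] for e in in_b])
        truth = np.array([0] * len(in_a) + [1] * len(in_b))
        agreements.append(max(float(np.mean(got == truth)), float(np.mean(got != truth))))
    agr = np.asarray(agreements, dtype=float)
    return dict(
        significant_rate=significant / n_replicates,
        mean_agreement=float(np.nanmean(agr)) if np.isfinite(agr).any() else 0.0,
        n_replicates=n_replicates,
    )
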