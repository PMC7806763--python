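"""End-to-end orchestration: cohort -> connectomes -> metrics -> NBS ->
characterization -> edge clustering -> modality classification.

A single :class:`PipelineConfig` (strict schema, JSON-loadable) drives the
run; every stage derives its seed deterministically from the global seed, so
a config + seed pair reproduces the whole results bundle byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import Atlas, generate_atlas
from .cohort import (DEFAULT_TR, GROUPS, CohortTimeSeries, PlantedEffect,
                     generate_cohort, generate_timeseries)
from .connectome import WaveletConfig, build_connectomes
from .graphmetrics import compare_global_metrics, global_metrics_table
from .nbs import NBSConfig, nbs_test, result_edge_table
from .characterize import (conjunction, degree_ranking, demographics_summary,
                           lobe_proportions, spearman_fdr)
from .edgecluster import EdgeKMeans, edge_profiles
from .modality_rf import classify_modality
from . import io as hio
from ._edges import edge_index

DEFAULT_CONTRASTS = (
    ("HC", "NC-H"),
    ("HC", "SCZ-H"),
    ("HC", "BD-H"),
    ("HC", "BD"),
    ("NC-H", "SCZ-H", "BD-H"),  # omnibus across hallucination groups
)

_SECTIONS = {"seed", "atlas", "cohort", "wavelet", "nbs", "contrasts", "cluster", "rf"}


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass


def _check_keys(d: dict, allowed: set, where: str) -> None:
    extra = set(d) - allowed
    if extra:
        raise ConfigError(f"unknown config keys in {where}: {sorted(extra)}")


@dataclass
class PipelineConfig:
    seed: int = 0
    atlas: dict = field(default_factory=lambda: {"n_nodes": 90, "scheme": "aal90-lobes"})
    cohort: dict = field(default_factory=dict)
    wavelet: dict = field(default_factory=dict)
    nbs: dict = field(default_factory=dict)
    contrasts: tuple = DEFAULT_CONTRASTS
    cluster: dict = field(default_factory=dict)
    rf: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        _check_keys(d, _SECTIONS, "top level")
        _check_keys(d.get("atlas", {}), {"n_nodes", "scheme"}, "atlas")
        _check_keys(
            d.get("cohort", {}),
            {"group_sizes", "timepoints", "sampling_interval", "effects",
             "motion_nuisance", "age_sex_coherence", "manifest", "subjects", "atlas_table"},
            "cohort",
        )
        _check_keys(d.get("wavelet", {}), {"level", "wavelet", "boundary", "nperseg", "noverlap", "window"}, "wavelet")
        _check_keys(d.get("nbs", {}), {"primary_threshold", "n_permutations", "covariates", "alpha", "permutation"}, "nbs")
        _check_keys(d.get("cluster", {}), {"k", "n_restarts", "zscore"}, "cluster")
        _check_keys(d.get("rf", {}), {"n_trees", "m_try"}, "rf")
        for contrast in d.get("contrasts", DEFAULT_CONTRASTS):
            bad = [g for g in contrast if g not in GROUPS]
            if bad:
                raise ConfigError(f"contrast references unknown groups {bad}")
        return cls(
            seed=d.get("seed", 0),
            atlas=d.get("atlas", {"n_nodes": 90, "scheme": "aal90-lobes"}),
            cohort=d.get("cohort", {}),
            wavelet=d.get("wavelet", {}),
            nbs=d.get("nbs", {}),
            contrasts=tuple(tuple(c) for c in d.get("contrasts", DEFAULT_CONTRASTS)),
            cluster=d.get("cluster", {}),
            rf=d.get("rf", {}),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return dict(seed=self.seed, atlas=self.atlas, cohort=self.cohort,
                    wavelet=self.wavelet, nbs=self.nbs,
                    contrasts=[list(c) for c in self.contrasts],
                    cluster=self.cluster, rf=self.rf)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def _parse_effects(effects: list[dict]) -> list[PlantedEffect]:
    out = []
    for e in effects:
        out.append(
            PlantedEffect(
                target_group=e["target_group"],
                edges=tuple(tuple(p) for p in e["edges"]),
                direction=e["direction"],
                shared_variance=e["shared_variance"],
                visual_only=e.get("visual_only", False),
            )
        )
    return out


def prepare_inputs(cfg: PipelineConfig):
    """Stage 1: simulate (or load) atlas, subject table and time series."""
    seeds = _stage_seeds(cfg.seed)
    if "manifest" in cfg.cohort:  # ingest a recorded cohort
        atlas = Atlas.from_tsv(cfg.cohort["atlas_table"])
        subjects = hio.read_subjects(cfg.cohort["subjects"])
        ts = hio.read_timeseries(cfg.cohort["manifest"])
        if ts.n_nodes != atlas.n_nodes:
            raise DataError("time series node count does not match the atlas")
        return atlas, subjects, ts
    atlas = generate_atlas(cfg.atlas.get("n_nodes", 90), cfg.atlas.get("scheme", "aal90-lobes"), seeds[0])
    subjects = generate_cohort(cfg.cohort.get("group_sizes"), seed=seeds[1])
    ts = generate_timeseries(
        subjects,
        atlas,
        _parse_effects(cfg.cohort.get("effects", [])),
        sampling_interval=cfg.cohort.get("sampling_interval", DEFAULT_TR),
        timepoints=cfg.cohort.get("timepoints", 256),
        seed=seeds[2],
        motion_nuisance=cfg.cohort.get("motion_nuisance", 0.0),
        age_sex_coherence=cfg.cohort.get("age_sex_coherence", 0.0),
    )
    return atlas, subjects, ts


def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute all stages; optionally write the results bundle under outdir."""
    seeds = _stage_seeds(cfg.seed)
    atlas, subjects, ts = prepare_inputs(cfg)
    wcfg = WaveletConfig(
        cfg.wavelet.get("level", 4), cfg.wavelet.get("wavelet", "sym4"),
        cfg.wavelet.get("boundary", "reflection"),
    )
    matrices = build_connectomes(ts, wcfg, nperseg=cfg.wavelet.get("nperseg"),
                                 noverlap=cfg.wavelet.get("noverlap"),
                                 window=cfg.wavelet.get("window", "hann"))

    metrics = global_metrics_table(matrices)
    covariates = tuple(cfg.nbs.get("covariates", ("age", "sex")))
    metric_comparison = compare_global_metrics(metrics, subjects, covariates)

    nbs_cfg = NBSConfig(
        primary_threshold=cfg.nbs.get("primary_threshold", 8.0),
        n_permutations=cfg.nbs.get("n_permutations", 10_000),
        covariates=covariates,
        alpha=cfg.nbs.get("alpha", 0.05),
        permutation=cfg.nbs.get("permutation", "freedman-lane"),
        seed=seeds[3],
    )
    nbs_results = {"-vs-".join(c): nbs_test(matrices, subjects, list(c), nbs_cfg) for c in cfg.contrasts}

    characterization: dict = {}
    sig_edge_sets = {}
    for name, res in nbs_results.items():
        entry = {"components": [dict(extent=c.extent, fwe_p=c.fwe_p, edges=c.edges) for c in res.components]}
        sig = res.significant_components
        if sig:
            edges = [e for c in sig for e in c.edges]
            entry["lobe_proportions"] = lobe_proportions(edges, atlas)
            entry["degree_ranking"] = degree_ranking(edges, atlas)
            sig_edge_sets[name] = set(edges)
        characterization[name] = entry
    if len(sig_edge_sets) >= 2:
        characterization["conjunction"] = conjunction(*sig_edge_sets.values())

    scored = subjects["symptom_score"].notna()
    symptom_correlations = None
    if scored.sum() >= 4:
        merged = metrics.merge(subjects[["subject_id", "symptom_score"]], on="subject_id")
        cols = ["global_efficiency_w", "clustering_w", "mst_leaf_fraction", "mst_diameter"]
        symptom_correlations = spearman_fdr(merged[cols], merged["symptom_score"])

    demographics = None
    if subjects["group"].nunique() >= 2:
        # only tabulate dichotomous variables with two observed levels
        dicho = tuple(v for v in ("sex", "has_auditory", "has_visual")
                      if subjects[v].nunique() >= 2)
        demographics = demographics_summary(subjects, dichotomous=dicho)

    # edge clustering on the omnibus (3-group) contrast's significant component
    clustering = None
    omnibus = [c for c in cfg.contrasts if len(c) >= 3]
    if omnibus:
        name = "-vs-".join(omnibus[0])
        res = nbs_results[name]
        comps = res.significant_components or res.components
        if comps:
            edges = comps[0].edges
            if len(edges) >= cfg.cluster.get("k", 6):
                prof = edge_profiles(edges, matrices, subjects, list(omnibus[0]), covariates)
                km = EdgeKMeans(
                    k=cfg.cluster.get("k", 6), n_restarts=cfg.cluster.get("n_restarts", 50),
                    random_state=seeds[4], zscore=cfg.cluster.get("zscore", False),
                ).fit(prof)
                clustering = dict(
                    contrast=name,
                    edges=[f"{i}--{j}" for i, j in edges],
                    labels=km.labels_,
                    summary=km.summary(),
                    inertia=km.inertia_,
                )

    # modality classification per hallucination group from its NBS edges
    rf_reports = {}
    iu, ju = edge_index(atlas.n_nodes)
    for group in ("NC-H", "SCZ-H", "BD-H"):
        name = f"HC-vs-{group}"
        if name not in nbs_results:
            continue
        res = nbs_results[name]
        comps = res.significant_components or res.components
        if not comps:
            continue
        edges = [e for c in comps for e in c.edges]
        gmask = subjects["group"] == group
        sub = subjects.loc[gmask]
        labels = pd.Series(np.where(sub["has_visual"], "visual", "auditory"), index=sub.index)
        if labels.nunique() < 2 or labels.value_counts().min() < 2:
            continue
        stack = np.stack([m.weights for m in matrices])[gmask.to_numpy()]
        feats = pd.DataFrame(
            {f"{atlas.labels[i]}__{atlas.labels[j]}": stack[:, i, j] for i, j in edges},
            index=sub.index,
        )
        rf_reports[group] = classify_modality(
            feats, labels, n_trees=cfg.rf.get("n_trees", 500),
            m_try=cfg.rf.get("m_try"), seed=seeds[5],
        )

    bundle = dict(
        manifest=dict(version=__version__, seed=cfg.seed, config_digest=cfg.digest(), config=cfg.to_dict()),
        atlas=atlas,
        subjects=subjects,
        metrics=metrics,
        metric_comparison=metric_comparison,
        demographics=demographics,
        nbs=nbs_results,
        characterization=characterization,
        symptom_correlations=symptom_correlations,
        clustering=clustering,
        rf=rf_reports,
    )
    if outdir is not None:
        _write_bundle(bundle, atlas, Path(outdir))
    return bundle


def _write_bundle(bundle: dict, atlas: Atlas, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    hio.write_json(bundle["manifest"], outdir / "run_manifest.json")
    atlas.to_tsv(outdir / "atlas.tsv")
    hio.write_subjects(bundle["subjects"], outdir / "subjects.tsv")
    (outdir / "metrics").mkdir(exist_ok=True)
    bundle["metrics"].to_csv(outdir / "metrics" / "global_metrics.tsv", sep="\t", index=False)
    bundle["metric_comparison"].to_csv(outdir / "metrics" / "group_comparison.tsv", sep="\t", index=False)
    if bundle["demographics"] is not None:
        hio.write_json(bundle["demographics"], outdir / "demographics.json")
    nbsdir = outdir / "nbs"
    nbsdir.mkdir(exist_ok=True)
    for name, res in bundle["nbs"].items():
        result_edge_table(res, atlas).to_csv(nbsdir / f"{name}_edges.tsv", sep="\t", index=False)
        hio.write_json(
            dict(
                groups=res.groups,
                threshold=res.threshold,
                components=[dict(extent=c.extent, fwe_p=c.fwe_p, edges=c.edges, nodes=c.nodes)
                            for c in res.components],
                null_max_extent=res.null_max_extent,
            ),
            nbsdir / f"{name}_result.json",
        )
    hio.write_json(
        {k: (dict(v, lobe_proportions=v["lobe_proportions"], degree_ranking=v["degree_ranking"])
             if "lobe_proportions" in v else v) if isinstance(v, dict) else v
         for k, v in bundle["characterization"].items()},
        outdir / "characterization.json",
    )
    if bundle["symptom_correlations"] is not None:
        bundle["symptom_correlations"].to_csv(outdir / "symptom_correlations.tsv", sep="\t", index=False)
    if bundle["clustering"] is not None:
        c = bundle["clustering"]
        pd.DataFrame(dict(edge=c["edges"], cluster=c["labels"])).to_csv(
            outdir / "edge_clusters.tsv", sep="\t", index=False)
        hio.write_json(dict(contrast=c["contrast"], inertia=c["inertia"], summary=c["summary"]),
                       outdir / "edge_cluster_summary.json")
    if bundle["rf"]:
        rep = {}
        for g, r in bundle["rf"].items():
            rep[g] = dict(weighted_accuracy=r.weighted_accuracy, sensitivity=r.sensitivity,
                          specificity=r.specificity, confusion=r.confusion, classes=r.classes,
                          vimp=r.vimp)
        hio.write_json(rep, outdir / "modality_rf.json")
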