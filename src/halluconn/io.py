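"""Plain-text readers/writers for every artifact the pipeline exchanges.

Formats: tab-delimited tables (atlas, subjects, metrics, edge lists),
one delimited matrix file per subject for time series and connectivity,
and JSON manifests/results.  Readers re-validate invariants on load.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import Atlas
from .cohort import CohortTimeSeries
from .connectome import ConnectivityMatrix

_NA = "NA"


def write_subjects(subjects: pd.DataFrame, path: str | Path) -> None:
    subjects.to_csv(path, sep="\t", index=False, na_rep=_NA)


def read_subjects(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[_NA])
    for col in ("has_auditory", "has_visual"):
        if df[col].dtype != bool:
            df[col] = df[col].astype(str).str.lower().map({"true": True, "false": False})
    return df


def write_timeseries(cohort: CohortTimeSeries, outdir: str | Path) -> Path:
    """One TSV per subject (rows=nodes, cols=timepoints) plus manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for sid, mat in zip(cohort.subject_ids, cohort.data):
        fname = f"{sid}_timeseries.tsv"
        np.savetxt(outdir / fname, mat, delimiter="\t")
        files.append(fname)
    manifest = dict(
        sampling_interval=cohort.sampling_interval,
        subject_ids=cohort.subject_ids,
        files=files,
        n_nodes=cohort.n_nodes,
        n_timepoints=cohort.n_timepoints,
    )
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def read_timeseries(manifest_path: str | Path) -> CohortTimeSeries:
    mpath = Path(manifest_path)
    m = json.loads(mpath.read_text())
    data = np.stack([np.loadtxt(mpath.parent / f, delimiter="\t") for f in m["files"]])
    return CohortTimeSeries(data, m["subject_ids"], m["sampling_interval"])


def write_connectomes(matrices: list[ConnectivityMatrix], outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for m in matrices:
        fname = f"{m.subject_id}_connectivity.tsv"
        np.savetxt(outdir / fname, m.weights, delimiter="\t")
        files.append(fname)
    manifest = dict(
        subject_ids=[m.subject_id for m in matrices],
        files=files,
        band=list(matrices[0].band),
        n_nodes=matrices[0].n_nodes,
    )
    mpath = outdir / "connectivity_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def read_connectomes(manifest_path: str | Path) -> list[ConnectivityMatrix]:
    mpath = Path(manifest_path)
    m = json.loads(mpath.read_text())
    band = tuple(m["band"])
    out = []
    for sid, f in zip(m["subject_ids"], m["files"]):
        w = np.loadtxt(mpath.parent / f, delimiter="\t")
        out.append(ConnectivityMatrix(w, sid, band))  # validates invariants
    return out


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (set, tuple)):
        return sorted(x) if isinstance(x, set) else list(x)
    if isinstance(x, pd.DataFrame):
        return x.to_dict(orient="list")
    if isinstance(x, pd.Series):
        return x.to_dict()
    raise TypeError(f"not JSON-serializable: {type(x)}")
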