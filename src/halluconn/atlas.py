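"""Node tables: region labels, lobe assignments, hemispheres.

The packaged ``aal90-lobes`` scheme reproduces the 90-region automated
anatomical labeling parcellation (cortex plus subcortex, no cerebellum)
grouped into six cerebral lobes.  Following the lobar convention common
in connectomics, the hippocampus and amygdala sit in the temporal lobe
while the caudate, putamen and pallidum (with the thalamus and the
peri-rolandic cortex) form the central lobe.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

LOBES = ("frontal", "temporal", "parietal", "occipital", "insula_cingulate", "central")

_COLUMNS = ["node_id", "label", "lobe", "hemisphere"]


@dataclass(frozen=True)
class Atlas:
    """Immutable node table defining edge indexing for all downstream stages.

    Attributes
    ----------
    table : pandas.DataFrame
        Columns ``node_id`` (contiguous 0..N-1), ``label`` (unique),
        ``lobe`` (one of :data:`LOBES`), ``hemisphere`` ({L, R, none}).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in _COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"atlas table missing columns {missing}")
        n = len(t)
        if not np.array_equal(t["node_id"].to_numpy(), np.arange(n)):
            raise ValueError("node_ids must be contiguous 0..N-1 in order")
        if t["label"].duplicated().any():
            raise ValueError("atlas labels must be unique")
        bad = set(t["lobe"]) - set(LOBES)
        if bad:
            raise ValueError(f"unknown lobe categories: {sorted(bad)}")
        if not set(t["hemisphere"]).issubset({"L", "R", "none"}):
            raise ValueError("hemisphere must be one of {L, R, none}")

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> list[str]:
        return self.table["label"].tolist()

    @property
    def lobes(self) -> np.ndarray:
        return self.table["lobe"].to_numpy()

    def nodes_in_lobe(self, lobe: str) -> np.ndarray:
        return self.table.loc[self.table["lobe"] == lobe, "node_id"].to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Atlas":
        return cls(pd.read_csv(path, sep="\t", dtype={"node_id": int}))


def _packaged_aal90() -> pd.DataFrame:
    with resources.files("halluconn.data").joinpath("aal90_lobes.tsv").open() as f:
        return pd.read_csv(f, sep="\t")


def generate_atlas(n_nodes: int, scheme: str = "aal90-lobes", seed: int = 0) -> Atlas:
    """Build a node table.

    Parameters
    ----------
    n_nodes : int
        Number of regions; must equal 90 for the fixed ``aal90-lobes`` scheme.
    scheme : {"aal90-lobes", "custom"}
        ``aal90-lobes`` loads the packaged lobe table; ``custom`` assigns
        lobes round-robin (seeded shuffle) so small toy atlases still cover
        several lobe categories.
    seed : int
        Used only by the ``custom`` scheme.
    """
    if n_nodes < 2:
        raise ValueError("an atlas needs at least 2 nodes")
    if scheme == "aal90-lobes":
        if n_nodes != 90:
            raise ValueError("scheme 'aal90-lobes' is fixed at 90 nodes")
        return Atlas(_packaged_aal90())
    if scheme == "custom":
        rng = np.random.default_rng(seed)
        lobes = np.array([LOBES[i % len(LOBES)] for i in range(n_nodes)])
        rng.shuffle(lobes)
        table = pd.DataFrame(
            {
                "node_id": np.arange(n_nodes),
                "label": [f"node_{i:03d}" for i in range(n_nodes)],
                "lobe": lobes,
                "hemisphere": "none",
            }
        )
        return Atlas(table)
    raise ValueError(f"unknown atlas scheme {scheme!r}")
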