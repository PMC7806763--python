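"""Upper-triangle edge indexing shared by all modules.

An edge is an unordered node pair (i, j) with i < j.  Vectorized edge
arrays enumerate edges in ``numpy.triu_indices`` order, which every
module in the package relies on for a consistent edge <-> column map.
"""

from __future__ import annotations

import numpy as np


def edge_index(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the upper triangle (the canonical edge order)."""
    return np.triu_indices(n_nodes, k=1)


def edge_list(n_nodes: int) -> list[tuple[int, int]]:
    iu, ju = edge_index(n_nodes)
    return list(zip(iu.tolist(), ju.tolist()))


def canonical_edge(i: int, j: int) -> tuple[int, int]:
    if i == j:
        raise ValueError(f"self-edge ({i},{i}) is not a valid edge")
    return (i, j) if i < j else (j, i)


def vectorize_matrices(mats: np.ndarray) -> np.ndarray:
    """Stack of symmetric (S, N, N) matrices -> (S, N*(N-1)/2) edge array."""
    mats = np.asarray(mats)
    if mats.ndim == 2:
        mats = mats[None]
    iu, ju = edge_index(mats.shape[-1])
    return mats[..., iu, ju]


def unvectorize(vec: np.ndarray, n_nodes: int, fill: float = 0.0) -> np.ndarray:
    """Edge vector -> symmetric matrix with ``fill`` on the diagonal."""
    vec = np.asarray(vec)
    out = np.full((n_nodes, n_nodes), fill, dtype=float)
    iu, ju = edge_index(n_nodes)
    out[iu, ju] = vec
    out[ju, iu] = vec
    np.fill_diagonal(out, fill)
    return out
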