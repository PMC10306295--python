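"""Topological (k-nearest-neighbor) interaction graphs.

Neighborhoods are topological, not metric: cell i interacts with its n_c
nearest cells by Euclidean distance, regardless of how far away they are.
Distance ties are broken by lower cell index so neighbor lists are fully
deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse


def knn_indices(positions: np.ndarray, n_c: int) -> np.ndarray:
    """Indices of each cell's ``n_c`` nearest neighbors (self excluded).

    Returns an (N, n_c) integer array.  Ties in distance are broken by lower
    index (stable argsort on the distance matrix).
    """
    pos = np.asarray(positions, dtype=float)
    n = pos.shape[0]
    if not 1 <= n_c <= n - 1:
        raise ValueError(f"n_c must be in [1, N-1]={n - 1}, got {n_c}")
    if n > 2000:
        # k-d tree avoids the O(N^2) distance matrix; exact ties in
        # continuous coordinates are measure-zero at this scale
        from scipy.spatial import cKDTree

        _, idx = cKDTree(pos).query(pos, k=n_c + 1)
        out = np.empty((n, n_c), dtype=np.int64)
        for i in range(n):
            row = idx[i][idx[i] != i]
            out[i] = row[:n_c]
        return out
    diff = pos[:, None, :] - pos[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    np.fill_diagonal(d2, np.inf)
    order = np.argsort(d2, axis=1, kind="stable")
    return order[:, :n_c]


def directed_adjacency(positions: np.ndarray, n_c: int) -> sparse.csr_matrix:
    """Boolean matrix m with m[i, j] = 1 iff j is one of i's n_c nearest."""
    nn = knn_indices(positions, n_c)
    n = nn.shape[0]
    rows = np.repeat(np.arange(n), n_c)
    m = sparse.csr_matrix(
        (np.ones(n * n_c), (rows, nn.ravel())), shape=(n, n)
    )
    return m


def symmetric_weights(positions: np.ndarray, n_c: int) -> sparse.csr_matrix:
    """Symmetrized pair weights n_ij: 1 mutual, 1/2 one-way, 0 otherwise."""
    m = directed_adjacency(positions, n_c)
    return (m + m.T) * 0.5


def csr_arrays(w: sparse.csr_matrix):
    """(indptr, indices, data) triple for the numba sampler."""
    w = w.tocsr()
    return (
        w.indptr.astype(np.int64),
        w.indices.astype(np.int64),
        w.data.astype(np.float64),
    )
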