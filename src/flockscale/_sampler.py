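r"""Numba Metropolis kernels for the nonlocally coupled XY model.

The target density over angle configurations {theta_i} is

    P({theta}) \propto exp( (J/2N) sum_i sum_{j in nc(i)} cos(theta_i - theta_j) )

where the inner sum runs over each cell's n_c topological (k-nearest)
neighbors.  Symmetrizing the ordered double sum gives pair weights
n_ij in {0, 1/2, 1} (1 for mutual neighbors, 1/2 one-way), so the
conditional log-density of a single spin is (J/N) sum_j n_ij cos(theta_i -
theta_j).  Kernels below implement a sequential single-site Metropolis scan
with Gaussian angle proposals; a dedicated all-to-all kernel keeps a running
resultant vector so each update is O(1) instead of O(N).
"""

from __future__ import annotations

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi


@njit(cache=True)
def _sweep_graph(theta, indptr, indices, weights, coupling, proposal_sd, n_sweeps):
    """Run ``n_sweeps`` Metropolis sweeps on a weighted neighbor graph.

    ``coupling`` is J/N.  ``theta`` is updated in place.
    """
    n = theta.shape[0]
    ct = np.cos(theta)
    st = np.sin(theta)
    for _ in range(n_sweeps):
        for i in range(n):
            old = theta[i]
            new = (old + proposal_sd * np.random.standard_normal()) % TWO_PI
            cos_n = np.cos(new)
            sin_n = np.sin(new)
            dc = cos_n - ct[i]
            ds = sin_n - st[i]
            hx = 0.0
            hy = 0.0
            for p in range(indptr[i], indptr[i + 1]):
                j = indices[p]
                w = weights[p]
                hx += w * ct[j]
                hy += w * st[j]
            delta = coupling * (dc * hx + ds * hy)
            if delta >= 0.0 or np.random.random() < np.exp(delta):
                theta[i] = new
                ct[i] = cos_n
                st[i] = sin_n
    return theta


@njit(cache=True)
def _sweep_complete(theta, coupling, proposal_sd, n_sweeps):
    """All-to-all variant: every pair is a mutual neighbor (weight 1).

    Maintains the resultant (sum_x, sum_y) so one update costs O(1).
    """
    n = theta.shape[0]
    sx = 0.0
    sy = 0.0
    for i in range(n):
        sx += np.cos(theta[i])
        sy += np.sin(theta[i])
    for _ in range(n_sweeps):
        for i in range(n):
            old = theta[i]
            cos_o = np.cos(old)
            sin_o = np.sin(old)
            new = (old + proposal_sd * np.random.standard_normal()) % TWO_PI
            cos_n = np.cos(new)
            sin_n = np.sin(new)
            hx = sx - cos_o
            hy = sy - sin_o
            delta = coupling * ((cos_n - cos_o) * hx + (sin_n - sin_o) * hy)
            if delta >= 0.0 or np.random.random() < np.exp(delta):
                theta[i] = new
                sx = hx + cos_n
                sy = hy + sin_n
    return theta


@njit(cache=True)
def _seed_numba(seed):
    np.random.seed(seed)


def run_chain(
    theta0: np.ndarray,
    indptr: np.ndarray,
    indices: np.ndarray,
    weights: np.ndarray,
    coupling: float,
    *,
    burn_in: int,
    n_samples: int,
    thin: int,
    proposal_sd: float,
    seed: int,
    complete: bool = False,
) -> np.ndarray:
    """Burn in, then collect ``n_samples`` configurations ``thin`` sweeps apart.

    Returns an (n_samples, N) array of angles in [0, 2pi).
    """
    theta = np.ascontiguousarray(theta0, dtype=np.float64).copy()
    _seed_numba(int(seed) & 0x7FFFFFFF)
    if complete:
        _sweep_complete(theta, coupling, proposal_sd, burn_in)
    else:
        _sweep_graph(theta, indptr, indices, weights, coupling, proposal_sd, burn_in)
    out = np.empty((n_samples, theta.shape[0]))
    for s in range(n_samples):
        if complete:
            _sweep_complete(theta, coupling, proposal_sd, thin)
        else:
            _sweep_graph(theta, indptr, indices, weights, coupling, proposal_sd, thin)
        out[s] = theta
    return out
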