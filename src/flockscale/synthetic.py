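r"""Synthetic data: positions, XY-model ensembles, noisy tracks, uniform nulls.

This module generates everything the downstream analysis stages need in the
absence of microscopy data: 2D cell position sets, equilibrium configurations
of unit velocity vectors drawn from the nonlocally coupled XY model, noisy
trajectories whose smoothed velocities reproduce those configurations, and
size-matched uniform-angle null datasets used as the disorder baseline.

The XY-model sampler is a single-site Metropolis chain (Gaussian angle
proposals, default SD 0.5 rad) over the density

    P({theta}) \propto exp( (J/2N) sum_i sum_{j in nc(i)} cos(theta_i - theta_j) )

with topological neighborhoods of size n_c and free boundary conditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _sampler, neighbors
from .trajectories import TrackSet

__all__ = [
    "PositionSet",
    "ModelParameters",
    "ConfigurationEnsemble",
    "generate_positions",
    "simulate_xy_ensemble",
    "synthesize_tracks",
    "generate_uniform_baseline",
    "ensemble_energy",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class PositionSet:
    """N cell positions (micrometers) inside a rectangular domain."""

    coordinates: np.ndarray  # (N, 2), um
    bounds: tuple[float, float, float, float]  # (xmin, xmax, ymin, ymax), um

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 2:
            raise ValueError("coordinates must be (N>=2, 2)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        xmin, xmax, ymin, ymax = self.bounds
        if not (xmax > xmin and ymax > ymin):
            raise ValueError("degenerate bounds")
        x, y = coords[:, 0], coords[:, 1]
        if x.min() < xmin or x.max() > xmax or y.min() < ymin or y.max() > ymax:
            raise ValueError("points outside declared bounds")
        # no exact duplicates: pairwise distances strictly positive
        if len(np.unique(coords, axis=0)) != len(coords):
            raise ValueError("duplicate positions")

    @property
    def n_cells(self) -> int:
        return self.coordinates.shape[0]


@dataclass(frozen=True)
class ModelParameters:
    """Nonlocal XY model parameters: coupling J >= 0, neighborhood size n_c."""

    J: float
    n_c: int

    def __post_init__(self):
        if not np.isfinite(self.J) or self.J < 0:
            raise ValueError("J must be finite and >= 0")
        if int(self.n_c) != self.n_c or self.n_c < 1:
            raise ValueError("n_c must be a positive integer")
        object.__setattr__(self, "n_c", int(self.n_c))

    def validate_for(self, n_cells: int) -> None:
        if self.n_c >= n_cells:
            raise ValueError(
                f"n_c={self.n_c} must be < N={n_cells} (each cell needs n_c others)"
            )


@dataclass
class ConfigurationEnsemble:
    """Equilibrium angle configurations plus sampler bookkeeping."""

    angles: np.ndarray  # (n_realizations, N), radians in [0, 2pi)
    energies: np.ndarray  # (n_realizations,)
    params: ModelParameters
    seed: int
    burn_in: int
    thin: int

    def __post_init__(self):
        a = np.asarray(self.angles, dtype=float)
        if a.ndim != 2:
            raise ValueError("angles must be (n_realizations, N)")
        if a.size and (a.min() < 0 or a.max() >= TWO_PI):
            raise ValueError("angles must lie in [0, 2pi)")
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("energies must be finite")
        self.angles = a

    @property
    def n_realizations(self) -> int:
        return self.angles.shape[0]

    def to_frame(self) -> pd.DataFrame:
        n_r, n = self.angles.shape
        return pd.DataFrame(
            {
                "realization": np.repeat(np.arange(n_r), n),
                "cell": np.tile(np.arange(n), n_r),
                "angle_rad": self.angles.ravel(),
            }
        )

    def write(self, csv_path: str | Path) -> None:
        """Plain CSV (realization, cell, angle) + JSON sidecar of metadata."""
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        meta = {
            "J": self.params.J,
            "n_c": self.params.n_c,
            "seed": self.seed,
            "burn_in_sweeps": self.burn_in,
            "thinning_sweeps": self.thin,
            "n_realizations": int(self.n_realizations),
        }
        csv_path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


def generate_positions(
    n_cells: int,
    mode: str = "uniform",
    bounds: tuple[float, float, float, float] = (0.0, 800.0, 0.0, 800.0),
    seed: int = 0,
    n_clusters: int = 5,
) -> PositionSet:
    """Draw ``n_cells`` distinct positions inside ``bounds``.

    ``uniform`` emulates a spatially homogeneous population;
    ``clustered`` draws from ``n_clusters`` Gaussian blobs (SD = 8% of the
    short side) to emulate locally dense patches, clipped to the domain.
    """
    if n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    xmin, xmax, ymin, ymax = map(float, bounds)
    rng = np.random.default_rng(seed)
    if mode == "uniform":
        coords = rng.uniform((xmin, ymin), (xmax, ymax), size=(n_cells, 2))
    elif mode == "clustered":
        sd = 0.08 * min(xmax - xmin, ymax - ymin)
        centers = rng.uniform((xmin, ymin), (xmax, ymax), size=(n_clusters, 2))
        which = rng.integers(0, n_clusters, size=n_cells)
        coords = centers[which] + rng.normal(0.0, sd, size=(n_cells, 2))
        coords[:, 0] = np.clip(coords[:, 0], xmin, xmax)
        coords[:, 1] = np.clip(coords[:, 1], ymin, ymax)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    # regenerate any exact duplicates (probability ~0, but the invariant is strict)
    while len(np.unique(coords, axis=0)) != len(coords):  # pragma: no cover
        _, idx = np.unique(coords, axis=0, return_index=True)
        dup = np.setdiff1d(np.arange(n_cells), idx)
        coords[dup] = rng.uniform((xmin, ymin), (xmax, ymax), size=(len(dup), 2))
    return PositionSet(coords, (xmin, xmax, ymin, ymax))


def ensemble_energy(
    angles: np.ndarray, positions: PositionSet, params: ModelParameters
) -> np.ndarray:
    r"""E({theta}) = -(J/2N) sum_{i,j} n_ij cos(theta_i - theta_j).

    The double sum runs over ordered pairs with the symmetrized weights
    n_ij in {0, 1/2, 1}; it equals the ordered neighbor sum in the model's
    exponent, so P \propto exp(-E).
    """
    angles = np.atleast_2d(np.asarray(angles, dtype=float))
    n = positions.n_cells
    w = neighbors.symmetric_weights(positions.coordinates, params.n_c).tocoo()
    diff = angles[:, w.row] - angles[:, w.col]
    return -(params.J / (2.0 * n)) * (np.cos(diff) @ w.data)


def simulate_xy_ensemble(
    positions: PositionSet,
    params: ModelParameters,
    n_realizations: int,
    seed: int = 0,
    burn_in: int = 1000,
    thin: int = 10,
    proposal_sd: float = 0.5,
    independent_chains: bool = False,
    init: str = "random",
) -> ConfigurationEnsemble:
    """Sample angle configurations from the nonlocal XY model.

    One Metropolis chain is burned in for ``burn_in`` sweeps and then sampled
    every ``thin`` sweeps (default); with ``independent_chains`` each
    realization comes from its own freshly seeded, fully burned-in chain,
    which is what the phase-diagram sweeps use so that across-realization
    variances are variances over independent samples.

    ``init`` is ``"random"`` (uniform angles) or ``"ordered"`` (all aligned
    along a random common direction).  Ordered starts avoid long-lived
    frozen vortex configurations deep in the ordered phase, where random
    starts equilibrate extremely slowly and inflate across-chain variances.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    params.validate_for(positions.n_cells)
    n = positions.n_cells
    complete = params.n_c == n - 1
    if complete:
        indptr = indices = weights = np.empty(0, dtype=np.int64)
        weights = np.empty(0, dtype=np.float64)
    else:
        indptr, indices, weights = neighbors.csr_arrays(
            neighbors.symmetric_weights(positions.coordinates, params.n_c)
        )
    coupling = params.J / n
    rng = np.random.default_rng(seed)

    if init not in ("random", "ordered"):
        raise ValueError(f"unknown init {init!r}")

    def _one_chain(n_samples: int, chain_seed: int) -> np.ndarray:
        if init == "ordered":
            theta0 = np.full(n, rng.uniform(0.0, TWO_PI))
        else:
            theta0 = rng.uniform(0.0, TWO_PI, size=n)
        return _sampler.run_chain(
            theta0,
            indptr,
            indices,
            weights,
            coupling,
            burn_in=burn_in,
            n_samples=n_samples,
            thin=thin,
            proposal_sd=proposal_sd,
            seed=chain_seed,
            complete=complete,
        )

    if independent_chains:
        chain_seeds = rng.integers(0, 2**31 - 1, size=n_realizations)
        samples = np.vstack(
            [_one_chain(1, int(s)) for s in chain_seeds]
        )
    else:
        samples = _one_chain(n_realizations, int(rng.integers(0, 2**31 - 1)))
    energies = ensemble_energy(samples, positions, params)
    return ConfigurationEnsemble(
        samples, energies, params, seed=seed, burn_in=burn_in, thin=thin
    )


def synthesize_tracks(
    positions: PositionSet,
    ensemble: ConfigurationEnsemble,
    speed: float = 1.0,
    frame_interval: float = 10.0,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> TrackSet:
    """Dress an ensemble as noisy trajectories.

    Realizations are read in sampler order as successive frames: each cell
    advances by ``speed * frame_interval`` along its current angle, and the
    observed positions carry isotropic Gaussian jitter of SD ``jitter_sd``
    (um).  Track length is n_realizations + 1 frames.  This is a kinematic
    dressing of equilibrium configurations, not a self-propelled dynamics.
    """
    if speed <= 0 or frame_interval <= 0:
        raise ValueError("speed and frame_interval must be positive")
    if ensemble.n_realizations == 0:
        raise ValueError("empty ensemble")
    rng = np.random.default_rng(seed)
    n_frames = ensemble.n_realizations + 1
    n = positions.n_cells
    if ensemble.angles.shape[1] != n:
        raise ValueError("ensemble and positions disagree on N")
    steps = speed * frame_interval * np.stack(
        [np.cos(ensemble.angles), np.sin(ensemble.angles)], axis=-1
    )  # (frames-1, N, 2)
    true_xy = np.concatenate(
        [positions.coordinates[None], positions.coordinates[None] + np.cumsum(steps, axis=0)],
        axis=0,
    )  # (frames, N, 2)
    obs = true_xy + rng.normal(0.0, jitter_sd, size=true_xy.shape) if jitter_sd > 0 else true_xy
    frames = np.tile(np.arange(n_frames)[:, None], (1, n))
    cells = np.tile(np.arange(n)[None, :], (n_frames, 1))
    df = pd.DataFrame(
        {
            "track_id": cells.ravel(),
            "frame": frames.ravel(),
            "x_um": obs[..., 0].ravel(),
            "y_um": obs[..., 1].ravel(),
        }
    ).sort_values(["track_id", "frame"], kind="stable")
    return TrackSet.from_frame(df, frame_interval=frame_interval)


def generate_uniform_baseline(
    n_datasets: int = 25,
    sizes: list[int] | np.ndarray = (100,),
    seed: int = 0,
) -> list[list[np.ndarray]]:
    """Size-matched uniform-angle null datasets.

    Returns ``n_datasets`` lists of angle arrays, one array per entry in
    ``sizes`` (e.g. per time point of the population being matched), each
    i.i.d. uniform on [0, 2pi).  These provide the disorder baseline band
    against which observed polarization is judged.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    sizes = [int(s) for s in np.atleast_1d(sizes)]
    if any(s < 1 for s in sizes):
        raise ValueError("sizes must be positive")
    rng = np.random.default_rng(seed)
    return [
        [rng.uniform(0.0, TWO_PI, size=s) for s in sizes] for _ in range(n_datasets)
    ]
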