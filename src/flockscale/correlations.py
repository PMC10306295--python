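"""Velocity-fluctuation correlation functions and their size scaling.

The spatial correlation of directional fluctuations is

    C(r) = < delta_s_i . delta_s_j >_r,   delta_s_i = s_i - <s>,

where <s> is the snapshot's mean unit velocity (the "moving reference
frame") and the average runs over all cell pairs separated by distance r.
Pairs from all time points are pooled into a single (distance, dot product)
list and C(r) is a moving average over a centered window (default +-100 um;
the box-scaling analysis uses +-50 um).

Because fluctuations sum to zero within a snapshot, the pair dot products
obey sum_{i!=j} delta_s_i . delta_s_j = -sum_i |delta_s_i|^2 < 0, so C(r)
must go negative somewhere; its first zero crossing r0 is the correlation
length.  Scale-free correlations are diagnosed by r0 growing linearly with
system size L, probed both across populations of different extent and by
subsampling randomly placed square boxes of width W (box scaling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .errors import NoCrossingError

logger = logging.getLogger(__name__)

__all__ = [
    "PairTable",
    "CorrelationFunction",
    "CorrelationLength",
    "SizeScalingResult",
    "BoxSample",
    "pair_table",
    "correlation_function",
    "estimate_r0",
    "system_size",
    "size_scaling_fit",
    "box_subsample",
    "box_scaling_curve",
]


@dataclass
class PairTable:
    """Pooled (separation, fluctuation dot product) pairs, sorted by r."""

    r: np.ndarray  # um, > 0
    dot: np.ndarray  # delta_s_i . delta_s_j
    snapshot_index: np.ndarray

    def __post_init__(self):
        order = np.argsort(self.r, kind="stable")
        self.r = np.asarray(self.r, dtype=float)[order]
        self.dot = np.asarray(self.dot, dtype=float)[order]
        self.snapshot_index = np.asarray(self.snapshot_index)[order]

    def __len__(self):
        return len(self.r)


@dataclass
class CorrelationFunction:
    """Moving-average C(r) with SEM on a regular grid.

    Entries where the window holds fewer than 2 pairs are NaN (undefined),
    never zero.
    """

    r: np.ndarray  # um, strictly increasing
    C: np.ndarray
    sem: np.ndarray
    n_pairs: np.ndarray
    window_halfwidth: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"r_um": self.r, "C": self.C, "sem": self.sem, "n_pairs": self.n_pairs}
        )


@dataclass
class CorrelationLength:
    """First zero crossing of C(r) and its uncertainty (both um)."""

    r0: float
    uncertainty: float


@dataclass
class SizeScalingResult:
    """r0 versus system size, with linear and logarithmic fits."""

    L: np.ndarray
    r0: np.ndarray
    r0_err: np.ndarray | None
    linear_slope: float
    linear_intercept: float
    linear_rho: float
    linear_p: float
    log_slope: float
    log_intercept: float
    log_rho: float
    log_p: float
    order_correlations: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def prefers_log(self) -> bool:
        """True when r0 ~ log L explains more variance than r0 ~ L."""
        return abs(self.log_rho) > abs(self.linear_rho)


@dataclass
class BoxSample:
    """Cells falling strictly inside one randomly placed W x W box."""

    width: float
    origin: tuple[float, float]
    snapshot_index: int
    cell_indices: np.ndarray


def pair_table(snapshots) -> PairTable:
    """All unordered pair separations and fluctuation dot products.

    The snapshot mean unit velocity is subtracted before forming dot
    products; pairs from all snapshots are pooled (every pair weighted
    equally, not every snapshot).
    """
    rs, dots, idx = [], [], []
    for k, snap in enumerate(snapshots):
        if snap.n_cells < 2:
            logger.warning("pair_table: skipping single-cell snapshot at t=%s", snap.time)
            continue
        ds = snap.unit_velocities - snap.unit_velocities.mean(axis=0)
        rs.append(pdist(snap.positions))
        dots.append(_pair_dots(ds))
        idx.append(np.full(rs[-1].shape, k))
    if not rs:
        raise ValueError("no snapshot with >= 2 cells")
    return PairTable(np.concatenate(rs), np.concatenate(dots), np.concatenate(idx))


def _pair_dots(ds: np.ndarray) -> np.ndarray:
    """Upper-triangle dot products delta_s_i . delta_s_j (pdist pair order)."""
    g = ds @ ds.T
    iu = np.triu_indices(len(ds), k=1)
    return g[iu]


def correlation_function(
    pairs: PairTable,
    window_halfwidth: float = 100.0,
    grid_step: float = 5.0,
) -> CorrelationFunction:
    """Moving-average correlation C(r) over windows [r - w, r + w].

    SEM is the sample SD of the dot products in the window divided by
    sqrt(count).  Prefix sums over the r-sorted pair list make each window
    O(log n).
    """
    if len(pairs) == 0:
        raise ValueError("empty pair table")
    r = pairs.r
    d = pairs.dot
    cum = np.concatenate([[0.0], np.cumsum(d)])
    cum2 = np.concatenate([[0.0], np.cumsum(d * d)])
    grid = np.arange(grid_step, r[-1] + grid_step / 2, grid_step)
    lo = np.searchsorted(r, grid - window_halfwidth, side="left")
    hi = np.searchsorted(r, grid + window_halfwidth, side="right")
    n = (hi - lo).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = (cum[hi] - cum[lo]) / n
        var = (cum2[hi] - cum2[lo]) / n - mean**2
        # unbiased SD / sqrt(n) reduces to sqrt(var / (n - 1))
        sem = np.sqrt(np.maximum(var, 0.0) / np.maximum(n - 1, 1))
    bad = n < 2
    mean[bad] = np.nan
    sem[bad] = np.nan
    return CorrelationFunction(grid, mean, sem, n.astype(int), window_halfwidth)


def estimate_r0(corr: CorrelationFunction) -> CorrelationLength:
    """First zero crossing of C(r), linearly interpolated.

    The uncertainty is half the width of the r interval around the crossing
    over which |C| <= its local SEM; it is floored at half a grid step so it
    is always positive.
    """
    valid = np.isfinite(corr.C)
    r = corr.r[valid]
    c = corr.C[valid]
    s = corr.sem[valid]
    if len(r) < 2 or c[0] <= 0:
        raise NoCrossingError("C(r) is not positive at the smallest defined r")
    sign_change = np.flatnonzero((c[:-1] > 0) & (c[1:] <= 0))
    if sign_change.size == 0:
        raise NoCrossingError("C(r) never crosses zero on the evaluated grid")
    i = int(sign_change[0])
    # linear interpolation between the bracketing grid points
    r0 = r[i] + (r[i + 1] - r[i]) * (c[i] / (c[i] - c[i + 1]))
    within = np.abs(c) <= s
    lo = i
    while lo > 0 and within[lo]:
        lo -= 1
    hi = i + 1
    while hi < len(r) - 1 and within[hi]:
        hi += 1
    step = r[1] - r[0] if len(r) > 1 else 1.0
    unc = max((r[hi] - r[lo]) / 2.0, step / 2.0)
    return CorrelationLength(float(r0), float(unc))


def system_size(snapshots, method: str = "max_separation") -> float:
    """Population size L (um): time average of a per-snapshot extent.

    ``max_separation``: maximum pairwise cell distance d_max per snapshot.
    ``convex_hull``: sqrt of the convex-hull area per snapshot (degenerate
    hulls -- e.g. collinear cells -- raise).
    """
    values = []
    for snap in snapshots:
        if snap.n_cells < 2:
            raise ValueError("system_size requires >= 2 cells per snapshot")
        if method == "max_separation":
            values.append(pdist(snap.positions).max())
        elif method == "convex_hull":
            try:
                hull = ConvexHull(snap.positions)
            except QhullError as e:
                raise ValueError(f"degenerate convex hull at t={snap.time}") from e
            if hull.volume <= 0:
                raise ValueError(f"degenerate convex hull at t={snap.time}")
            values.append(np.sqrt(hull.volume))  # 2D "volume" is the area
        else:
            raise ValueError(f"unknown method {method!r}")
    return float(np.mean(values))


def size_scaling_fit(
    L: np.ndarray,
    r0: np.ndarray,
    r0_err: np.ndarray | None = None,
    order_parameters: dict[str, np.ndarray] | None = None,
) -> SizeScalingResult:
    """OLS fits of r0 on L and on log L, with Pearson correlations.

    ``order_parameters`` maps names (e.g. "polarization") to per-population
    values; each gets a Pearson rho and two-sided p against r0.
    """
    L = np.asarray(L, dtype=float)
    r0 = np.asarray(r0, dtype=float)
    if len(L) < 3:
        raise ValueError("need >= 3 populations to fit")
    if np.ptp(L) == 0:
        raise ValueError("degenerate (constant) L values")
    lin = stats.linregress(L, r0)
    logf = stats.linregress(np.log(L), r0)
    extras = {}
    for name, vals in (order_parameters or {}).items():
        rho, p = stats.pearsonr(np.asarray(vals, dtype=float), r0)
        extras[name] = (float(rho), float(p))
    return SizeScalingResult(
        L=L,
        r0=r0,
        r0_err=None if r0_err is None else np.asarray(r0_err, dtype=float),
        linear_slope=float(lin.slope),
        linear_intercept=float(lin.intercept),
        linear_rho=float(lin.rvalue),
        linear_p=float(lin.pvalue),
        log_slope=float(logf.slope),
        log_intercept=float(logf.intercept),
        log_rho=float(logf.rvalue),
        log_p=float(logf.pvalue),
        order_correlations=extras,
    )


def _field_of_view(snapshots) -> tuple[float, float, float, float]:
    mins = np.full(2, np.inf)
    maxs = np.full(2, -np.inf)
    for snap in snapshots:
        mins = np.minimum(mins, snap.positions.min(axis=0))
        maxs = np.maximum(maxs, snap.positions.max(axis=0))
    return mins[0], maxs[0], mins[1], maxs[1]


def box_subsample(
    snapshots, W: float, boxes_per_snapshot: int = 30, seed: int = 0
) -> list[BoxSample]:
    """Randomly placed W x W boxes fully inside the field of view.

    Cells strictly inside a box are selected; 30 boxes per snapshot by
    default.
    """
    xmin, xmax, ymin, ymax = _field_of_view(snapshots)
    if W <= 0:
        raise ValueError("W must be positive")
    if W > min(xmax - xmin, ymax - ymin):
        raise ValueError(
            f"W={W} exceeds the field of view "
            f"({xmax - xmin:.1f} x {ymax - ymin:.1f} um)"
        )
    rng = np.random.default_rng(seed)
    samples = []
    for k, snap in enumerate(snapshots):
        ox = rng.uniform(xmin, xmax - W, size=boxes_per_snapshot)
        oy = rng.uniform(ymin, ymax - W, size=boxes_per_snapshot)
        for b in range(boxes_per_snapshot):
            p = snap.positions
            inside = (
                (p[:, 0] > ox[b])
                & (p[:, 0] < ox[b] + W)
                & (p[:, 1] > oy[b])
                & (p[:, 1] < oy[b] + W)
            )
            samples.append(
                BoxSample(
                    width=W,
                    origin=(float(ox[b]), float(oy[b])),
                    snapshot_index=k,
                    cell_indices=np.flatnonzero(inside),
                )
            )
    return samples


def box_correlation(
    snapshots,
    W: float,
    boxes_per_snapshot: int = 30,
    window_halfwidth: float = 50.0,
    grid_step: float = 5.0,
    seed: int = 0,
    local_mean: bool = True,
) -> CorrelationFunction:
    """Pooled correlation function C_W(r) for one box width.

    Each box is treated as a subsystem: fluctuations are taken about the
    box's own mean unit velocity (``local_mean=True``, the default
    convention) before pair dot products are pooled across all boxes.
    """
    snaps = list(snapshots)
    boxes = box_subsample(snaps, W, boxes_per_snapshot, seed)
    rs, dots = [], []
    for box in boxes:
        snap = snaps[box.snapshot_index]
        idx = box.cell_indices
        if idx.size < 2:
            continue
        u = snap.unit_velocities[idx]
        ds = u - u.mean(axis=0) if local_mean else u - snap.unit_velocities.mean(axis=0)
        rs.append(pdist(snap.positions[idx]))
        dots.append(_pair_dots(ds))
    if not rs:
        raise ValueError(f"no box of width {W} contained >= 2 cells")
    pairs = PairTable(
        np.concatenate(rs), np.concatenate(dots), np.zeros(sum(map(len, rs)), dtype=int)
    )
    return correlation_function(pairs, window_halfwidth, grid_step)


def box_scaling_curve(
    snapshots,
    widths,
    boxes_per_snapshot: int = 30,
    window_halfwidth: float = 50.0,
    grid_step: float = 5.0,
    seed: int = 0,
    local_mean: bool = True,
) -> SizeScalingResult:
    """r0(W) over a set of box widths, with linear and log fits.

    Widths whose boxes average fewer than 2 cells, or whose C_W(r) never
    crosses zero, are excluded with a warning.
    """
    widths = list(widths)
    if len(widths) < 3:
        raise ValueError("need >= 3 box widths")
    if max(widths) < 2 * min(widths):
        raise ValueError("widths should span at least a 2x range")
    snaps = list(snapshots)
    Ws, r0s, errs = [], [], []
    for i, W in enumerate(sorted(widths)):
        try:
            corr = box_correlation(
                snaps,
                W,
                boxes_per_snapshot,
                window_halfwidth,
                grid_step,
                seed=seed + i,
                local_mean=local_mean,
            )
            est = estimate_r0(corr)
        except (ValueError, NoCrossingError) as e:
            logger.warning("box width %s excluded: %s", W, e)
            continue
        Ws.append(W)
        r0s.append(est.r0)
        errs.append(est.uncertainty)
    if len(Ws) < 3:
        raise ValueError("fewer than 3 box widths yielded a correlation length")
    return size_scaling_fit(np.array(Ws), np.array(r0s), np.array(errs))
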