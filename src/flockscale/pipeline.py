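"""End-to-end analysis orchestration with a reproducible manifest.

``run_analysis`` drives tracks -> smoothing -> velocities -> order metrics
-> classification -> correlation function -> r0 -> system size, then the
cross-population size-scaling fit, optional box scaling, and the
maximum-entropy fit, writing the CSV/JSON artifacts of each stage plus a
manifest recording versions, parameters, the master seed, and per-stage
status.  A stage failure is recorded and its dependents skipped; unrelated
stages still run.  ``simulate_dataset`` writes synthetic track bundles with
ground truth for recovery tests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, correlations, maxent, order, synthetic, trajectories
from .errors import FlockscaleError

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_analysis", "simulate_dataset"]


@dataclass
class AnalysisConfig:
    """Knobs of the full pipeline (units in the field names)."""

    frame_interval_min: float = 10.0
    smoothing: bool = True
    window_um: float = 100.0
    box_window_um: float = 50.0
    grid_step_um: float = 5.0
    box_widths_um: tuple = (200.0, 300.0, 400.0, 500.0, 600.0, 700.0, 800.0)
    n_boxes: int = 30
    size_method: str = "max_separation"
    nc_grid: tuple | None = None  # None -> log-spaced default per population
    n_null_datasets: int = 25
    seed: int = 0
    out_dir: str = "flockscale_out"

    def __post_init__(self):
        positive = {
            "frame_interval_min": self.frame_interval_min,
            "window_um": self.window_um,
            "box_window_um": self.box_window_um,
            "grid_step_um": self.grid_step_um,
            "n_boxes": self.n_boxes,
            "n_null_datasets": self.n_null_datasets,
        }
        for name, v in positive.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if any(w <= 0 for w in self.box_widths_um):
            raise ValueError("box widths must be positive")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default, allow_nan=True))


def run_analysis(config: AnalysisConfig, track_files: list, dialect: str = "simple_csv") -> dict:
    """Run the full pipeline on one or more track files (one population each).

    Returns the manifest dict (also written to ``out_dir/manifest.json``).
    """
    if not track_files:
        raise ValueError("need at least one track file")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "flockscale_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "populations": {},
        "stages": {},
    }
    rng = np.random.default_rng(config.seed)
    per_pop: dict[str, dict] = {}
    Ls, r0s, r0errs, pols, nems = [], [], [], [], []

    for path in track_files:
        name = Path(path).stem
        pdir = out / name
        pdir.mkdir(exist_ok=True)
        record: dict = {"stages": {}, "exclusions": {}}
        per_pop[name] = record
        try:
            tracks = trajectories.read_tracks(
                path, dialect=dialect, frame_interval=config.frame_interval_min
            )
            smooth = trajectories.gaussian_smooth(tracks) if config.smoothing else tracks
            series = trajectories.estimate_velocities(smooth)
            if len(series) == 0:
                raise FlockscaleError("no usable snapshots after smoothing")
            record["exclusions"]["zero_velocity"] = series.n_zero_velocity_excluded
            series.to_frame().to_csv(pdir / "snapshots.csv", index=False)
            record["stages"]["snapshots"] = "ok"
        except Exception as e:  # noqa: BLE001 - recorded, dependents skipped
            record["stages"]["snapshots"] = f"failed: {e}"
            logger.error("population %s: snapshot stage failed: %s", name, e)
            continue

        sizes = [s.n_cells for s in series]
        baseline = synthetic.generate_uniform_baseline(
            config.n_null_datasets, sizes, seed=int(rng.integers(0, 2**31 - 1))
        )
        try:
            oseries = order.polarization_series(series, baseline_datasets=baseline)
            oseries.to_frame().to_csv(pdir / "order_series.csv", index=False)
            pols.append(float(np.mean(oseries.polarization)))
            nems.append(float(np.mean(oseries.nematic)))
            record["stages"]["order_metrics"] = "ok"
        except Exception as e:  # noqa: BLE001
            record["stages"]["order_metrics"] = f"failed: {e}"
        try:
            pooled = np.concatenate([s.angles for s in series])
            cls = order.classify_population(pooled)
            _write_json(
                pdir / "classification.json",
                {
                    "label": cls.label,
                    "log_likelihoods": cls.log_likelihoods,
                    "scores": cls.scores,
                    "parameters": cls.parameters,
                    "n_angles": cls.n_angles,
                    "reliable": cls.reliable,
                },
            )
            record["classification"] = cls.label
            record["stages"]["classification"] = "ok"
        except Exception as e:  # noqa: BLE001
            record["stages"]["classification"] = f"failed: {e}"
        try:
            pairs = correlations.pair_table(series)
            corr = correlations.correlation_function(
                pairs, config.window_um, config.grid_step_um
            )
            corr.to_frame().to_csv(pdir / "correlation.csv", index=False)
            r0 = correlations.estimate_r0(corr)
            L = correlations.system_size(series, config.size_method)
            _write_json(
                pdir / "correlation_length.json",
                {"r0_um": r0.r0, "r0_err_um": r0.uncertainty, "L_um": L},
            )
            Ls.append(L)
            r0s.append(r0.r0)
            r0errs.append(r0.uncertainty)
            record["r0_um"] = r0.r0
            record["L_um"] = L
            record["stages"]["correlations"] = "ok"
        except Exception as e:  # noqa: BLE001
            record["stages"]["correlations"] = f"failed: {e}"
        try:
            fit = maxent.fit_maxent(
                list(series),
                nc_grid=config.nc_grid,
            )
            _write_json(
                pdir / "maxent_fit.json",
                {
                    "nc_star": fit.nc_star,
                    "J_star": fit.J_star,
                    "C_int": fit.c_int,
                    "nc_grid": fit.nc_grid,
                    "logL_profile": fit.log_likelihood,
                    "J_profile": fit.J_profile,
                    "polarization": fit.polarization,
                    "low_confidence": fit.low_confidence,
                    "flags": fit.flags,
                },
            )
            record["maxent"] = {"nc_star": fit.nc_star, "J_star": fit.J_star}
            record["stages"]["maxent"] = "ok"
        except Exception as e:  # noqa: BLE001
            record["stages"]["maxent"] = f"failed: {e}"

    manifest["populations"] = per_pop
    if len(r0s) >= 3:
        try:
            scaling = correlations.size_scaling_fit(
                np.array(Ls),
                np.array(r0s),
                np.array(r0errs),
                order_parameters={
                    "polarization": np.array(pols),
                    "nematic": np.array(nems),
                },
            )
            _write_json(
                out / "size_scaling.json",
                {
                    "L_um": scaling.L,
                    "r0_um": scaling.r0,
                    "linear": {
                        "slope": scaling.linear_slope,
                        "intercept": scaling.linear_intercept,
                        "rho": scaling.linear_rho,
                        "p": scaling.linear_p,
                    },
                    "log": {
                        "slope": scaling.log_slope,
                        "intercept": scaling.log_intercept,
                        "rho": scaling.log_rho,
                        "p": scaling.log_p,
                    },
                    "order_correlations": scaling.order_correlations,
                },
            )
            manifest["stages"]["size_scaling"] = "ok"
        except Exception as e:  # noqa: BLE001
            manifest["stages"]["size_scaling"] = f"failed: {e}"
    else:
        manifest["stages"]["size_scaling"] = "skipped: fewer than 3 populations with r0"

    _write_json(out / "manifest.json", manifest)
    return manifest


def simulate_dataset(
    n_cells: int = 50,
    n_frames: int = 20,
    J: float = 1.0,
    n_c: int = 5,
    speed: float = 1.0,
    frame_interval: float = 10.0,
    jitter_sd: float = 0.5,
    bounds: tuple = (0.0, 800.0, 0.0, 800.0),
    seed: int = 0,
    out_dir: str | Path = "flockscale_sim",
) -> dict:
    """Write a synthetic track bundle plus ground truth for recovery tests."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    positions = synthetic.generate_positions(n_cells, "uniform", bounds, seed=seed)
    params = synthetic.ModelParameters(J, n_c)
    ensemble = synthetic.simulate_xy_ensemble(
        positions, params, n_realizations=n_frames - 1, seed=seed + 1
    )
    tracks = synthetic.synthesize_tracks(
        positions,
        ensemble,
        speed=speed,
        frame_interval=frame_interval,
        jitter_sd=jitter_sd,
        seed=seed + 2,
    )
    trajectories.write_tracks(tracks, out / "tracks.csv")
    ensemble.write(out / "ensemble.csv")
    truth = {
        "J": J,
        "n_c": n_c,
        "n_cells": n_cells,
        "n_frames": n_frames,
        "speed_um_min": speed,
        "frame_interval_min": frame_interval,
        "jitter_sd_um": jitter_sd,
        "bounds_um": list(bounds),
        "seed": seed,
    }
    _write_json(out / "ground_truth.json", truth)
    return truth
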