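"""End-to-end pipeline: hydraulics → simulate → metrics → render.

Also houses the on-disk representations: dense snapshot-field CSVs
(header row of x coordinates, one row per y), the per-step metrics CSV,
observation CSVs, and the JSON run manifest.  All numeric CSV output is at
12 significant digits so reruns with the same config are byte-identical.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, config_hash, read_table, write_table
from .errors import InvalidInputError, MochipError
from .hydraulics import summarize
from .metrics import axial_variance, homogenization_time, mixing_cv
from .render import render_snapshots
from .synthetic import ObservationSet
from .transport import Grid, Trajectory, simulate
from .types import TracerField

__all__ = [
    "write_field_csv",
    "read_field_csv",
    "write_metrics_csv",
    "write_observations_csv",
    "read_observations_csv",
    "summary_metrics_frame",
    "RunManifest",
    "run_pipeline",
]

log = logging.getLogger("mochip")

_FIELD_RE = re.compile(r"fields_t(?P<t>[0-9.]+)s\.csv$")


def field_filename(time: float) -> str:
    return f"fields_t{time:.3f}s.csv"


def write_field_csv(field: TracerField, out_dir) -> Path:
    """Write one snapshot as dense CSV: y_mm column, one column per x cell."""
    g = field.grid
    frame = pd.DataFrame(
        field.concentration,
        columns=[f"x={xi:.9g}" for xi in g.x],
    )
    frame.insert(0, "y_m", g.y)
    return write_table(frame, Path(out_dir) / field_filename(field.time))


def read_field_csv(path) -> TracerField:
    """Re-read a snapshot CSV written by :func:`write_field_csv`."""
    path = Path(path)
    m = _FIELD_RE.search(path.name)
    if not m:
        raise InvalidInputError(
            f"{path.name} is not a snapshot field CSV (fields_t<time>s.csv)"
        )
    frame = read_table(path)
    y = frame["y_m"].to_numpy()
    xcols = [c for c in frame.columns if c.startswith("x=")]
    x = np.array([float(c[2:]) for c in xcols])
    conc = frame[xcols].to_numpy()
    nx, ny = len(x), len(y)
    grid = Grid(nx=nx, ny=ny, dx=float(x[1] - x[0]), dy=float(y[1] - y[0]))
    return TracerField(concentration=conc, grid=grid, time=float(m["t"]))


def write_metrics_csv(traj: Trajectory, out_dir) -> Path:
    frame = pd.DataFrame(
        {"time_s": traj.times, "total_mass": traj.total_mass, "com_x_m": traj.com_x}
    )
    return write_table(frame, Path(out_dir) / "metrics.csv")


def write_observations_csv(obs: ObservationSet, path) -> Path:
    """Observation CSV: time_s, com_x_m, then one intensity column per x."""
    frame = pd.DataFrame(obs.profiles, columns=[f"x={xi:.9g}" for xi in obs.x])
    frame.insert(0, "com_x_m", obs.com_x)
    frame.insert(0, "time_s", obs.times)
    return write_table(frame, path)


def read_observations_csv(path) -> ObservationSet:
    frame = read_table(path)
    xcols = [c for c in frame.columns if c.startswith("x=")]
    if not xcols or "time_s" not in frame or "com_x_m" not in frame:
        raise InvalidInputError(
            f"{path}: not an observation CSV (need time_s, com_x_m, x=… columns)"
        )
    return ObservationSet(
        times=frame["time_s"].to_numpy(),
        x=np.array([float(c[2:]) for c in xcols]),
        profiles=frame[xcols].to_numpy(),
        com_x=frame["com_x_m"].to_numpy(),
    )


def summary_metrics_frame(
    fields: list[TracerField],
    n_segments: int = 5,
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Snapshot-level summary: mixing CV and axial variance per stored field,
    plus the homogenization time estimated from that CV series."""
    fields = sorted(fields, key=lambda f: f.time)
    times = np.array([f.time for f in fields])
    cv = np.array([mixing_cv(f, n_segments) for f in fields])
    var = np.array([axial_variance(f) for f in fields])
    t_h = homogenization_time(times, cv, threshold)
    return pd.DataFrame(
        {
            "time_s": times,
            "mixing_cv": cv,
            "axial_variance_m2": var,
            "homogenization_time_s": [t_h if t_h is not None else np.nan] * len(times),
            "n_segments": [n_segments] * len(times),
            "cv_threshold": [threshold] * len(times),
        }
    )


@dataclass(frozen=True)
class RunManifest:
    """Provenance record written once per pipeline run."""

    config_sha256: str
    package_version: str
    seed: int
    started_utc: str
    finished_utc: str
    outputs: tuple[str, ...]
    complete: bool

    def write(self, out_dir) -> Path:
        path = Path(out_dir) / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.__dict__ | {"outputs": list(self.outputs)}, fh, indent=2)
            fh.write("\n")
        return path


def run_pipeline(run: RunConfig, out_dir, render: bool = True) -> RunManifest:
    """Execute the full analysis for one configuration.

    Writes flow_summary.csv, one fields_t<time>s.csv and (optionally) one
    PNG per snapshot, metrics.csv, summary_metrics.csv, and manifest.json.
    Rerunning with the same config reproduces the CSVs byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()
    sim = run.simulation
    outputs: list[Path] = []

    from .transport import stable_dt  # local import to avoid cycle at module load

    log.info(
        "run: grid %dx%d (dx=%.4g m, dy=%.4g m), dt=%.4g s, V_peak=%.4g m/s, "
        "f=%.4g Hz, D=%.3g m²/s, Q=%.4g m³/s",
        sim.nx, sim.ny, sim.grid().dx, sim.grid().dy, stable_dt(sim),
        sim.protocol.mean_velocity_amplitude, sim.protocol.frequency_hz,
        sim.tracer.diffusivity, run.flow_rate,
    )

    summary = summarize(
        sim.geometry, sim.fluid, sim.protocol, sim.tracer,
        run.flow_rate, run.path_length,
    )
    outputs.append(
        write_table(pd.DataFrame([summary.as_dict()]), out / "flow_summary.csv")
    )

    traj = simulate(sim)
    for snap in traj.snapshots:
        outputs.append(write_field_csv(snap, out))
    outputs.append(write_metrics_csv(traj, out))
    outputs.append(
        write_table(
            summary_metrics_frame(
                list(traj.snapshots), n_segments=sim.n_record_segments
            ),
            out / "summary_metrics.csv",
        )
    )
    if render:
        outputs.extend(render_snapshots(traj, out))

    manifest = RunManifest(
        config_sha256=config_hash(run),
        package_version=__version__,
        seed=sim.seed,
        started_utc=started,
        finished_utc=datetime.now(timezone.utc).isoformat(),
        outputs=tuple(p.name for p in outputs),
        complete=True,
    )
    manifest.write(out)
    return manifest
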