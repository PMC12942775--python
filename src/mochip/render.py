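"""Snapshot rendering: concentration heatmaps with velocity arrows.

One PNG per snapshot over the axial × vertical domain, with a common color
normalization across frames (so intensities are comparable) and quiver
arrows showing the instantaneous axial velocity profile u(y, t).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .errors import InvalidInputError
from .rocking import velocity_profile
from .transport import Trajectory

__all__ = ["snapshot_filename", "render_snapshots"]


def snapshot_filename(time: float) -> str:
    return f"snapshot_t{time:08.3f}s.png"


def render_snapshots(
    traj: Trajectory, out_dir, n_arrow_cols: int = 8, dpi: int = 120
) -> list[Path]:
    """Write one heatmap + velocity-arrow PNG per snapshot; return the paths.

    Color limits are fixed across all frames (0 to the global maximum) so the
    progressive smearing of the tracer is visible as fading, not rescaling.
    """
    if not traj.snapshots:
        raise InvalidInputError("trajectory has no snapshots to render")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = traj.config
    g = traj.grid
    vmax = max(float(s.concentration.max()) for s in traj.snapshots)
    vmax = vmax if vmax > 0 else 1.0
    L, H = cfg.geometry.length, cfg.geometry.height
    xq = np.linspace(0.1 * L, 0.9 * L, n_arrow_cols)
    yq = g.y[:: max(1, g.ny // 6)]
    u_scale = max(1.5 * cfg.protocol.mean_velocity_amplitude, 1e-12)

    paths: list[Path] = []
    for snap in traj.snapshots:
        fig, ax = plt.subplots(figsize=(8, 1.6), constrained_layout=True)
        im = ax.imshow(
            snap.concentration,
            origin="lower",
            extent=(0, L * 1e3, 0, H * 1e3),
            aspect="auto",
            cmap="viridis",
            vmin=0.0,
            vmax=vmax,
        )
        u = np.asarray(velocity_profile(yq, snap.time, cfg.geometry, cfg.protocol))
        X, Y = np.meshgrid(xq * 1e3, yq * 1e3)
        U = np.tile(u[:, None], (1, n_arrow_cols))
        ax.quiver(
            X, Y, U, np.zeros_like(U),
            color="white", scale=u_scale * 12, scale_units="width", width=3e-3,
        )
        ax.set_xlabel("x (mm)")
        ax.set_ylabel("y (mm)")
        ax.set_title(f"t = {snap.time:g} s")
        fig.colorbar(im, ax=ax, label="C (a.u.)")
        path = out / snapshot_filename(snap.time)
        fig.savefig(path, dpi=dpi)
        plt.close(fig)
        paths.append(path)
    return paths
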