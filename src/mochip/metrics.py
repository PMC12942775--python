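"""Quantitative summaries of tracer fields and trajectories.

Mass, center of mass, axial variance, a segment-based mixing coefficient of
variation (the five default segments mirror the device's five aligned
chambers as a 1D proxy), homogenization time, and the oscillation period of
the center of mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .types import TracerField
from .transport import Trajectory

__all__ = [
    "total_mass",
    "center_of_mass_x",
    "axial_variance",
    "mixing_cv",
    "segment_cv",
    "homogenization_time",
    "oscillation_period",
    "TrajectoryMetrics",
    "trajectory_metrics",
]


def total_mass(field: TracerField) -> float:
    """Total tracer mass Σ C·dx·dy (concentration units × m²)."""
    return float(field.concentration.sum()) * field.grid.cell_area


def _weighted_x_moments(field: TracerField):
    prof = field.concentration.sum(axis=0)
    m = prof.sum()
    if m <= 0:
        raise InvalidInputError("field has zero total mass")
    x = field.grid.x
    com = float((x * prof).sum() / m)
    var = float(((x - com) ** 2 * prof).sum() / m)
    return com, var


def center_of_mass_x(field: TracerField) -> float:
    """Mass-weighted mean axial position, meters (cell-center convention)."""
    return _weighted_x_moments(field)[0]


def axial_variance(field: TracerField) -> float:
    """Mass-weighted variance of the axial position, m².

    For pure diffusion of a Gaussian far from the walls this grows as
    σ²(t) = σ₀² + 2Dt.
    """
    return _weighted_x_moments(field)[1]


def segment_cv(values: np.ndarray) -> float:
    """Population coefficient of variation std/mean of segment means."""
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    if mean == 0:
        raise InvalidInputError("segment means have zero mean")
    return float(values.std(ddof=0) / mean)


def mixing_cv(field: TracerField, n_segments: int = 5) -> float:
    """Coefficient of variation of mean concentration across equal axial
    segments: 0 for a perfectly homogenized channel, 2.0 when all tracer
    sits in one of five segments.  Invariant under global scaling of C."""
    if n_segments < 2:
        raise InvalidInputError(f"n_segments must be >= 2, got {n_segments}")
    seg = [s.mean() for s in np.array_split(field.concentration, n_segments, axis=1)]
    return segment_cv(np.asarray(seg))


def homogenization_time(
    times: np.ndarray, cv_series: np.ndarray, threshold: float = 0.05
) -> float | None:
    """First time the mixing CV drops strictly below ``threshold``.

    Linear interpolation between the bracketing samples; ``None`` if the
    threshold is never reached.
    """
    times = np.asarray(times, dtype=float)
    cv = np.asarray(cv_series, dtype=float)
    if times.shape != cv.shape:
        raise InvalidInputError("times and cv_series lengths differ")
    below = cv < threshold
    if not below.any():
        return None
    k = int(np.argmax(below))
    if k == 0:
        return float(times[0])
    t0, t1 = times[k - 1], times[k]
    c0, c1 = cv[k - 1], cv[k]
    if c0 == c1:
        return float(t1)
    return float(t0 + (c0 - threshold) / (c0 - c1) * (t1 - t0))


def oscillation_period(times: np.ndarray, com_x: np.ndarray) -> float:
    """Oscillation period of the center-of-mass trajectory, seconds.

    Detected from zero crossings of the center-of-mass velocity (finite
    differences): the period is twice the mean spacing between successive
    velocity sign changes (turning points of com_x).
    """
    times = np.asarray(times, dtype=float)
    com = np.asarray(com_x, dtype=float)
    if len(times) < 4:
        raise InvalidInputError("need at least 4 samples to estimate a period")
    v = np.diff(com) / np.diff(times)
    tv = 0.5 * (times[:-1] + times[1:])
    sign = np.sign(v)
    nz = sign != 0
    sign, tv = sign[nz], tv[nz]
    flips = np.nonzero(np.diff(sign) != 0)[0]
    if len(flips) < 2:
        raise InvalidInputError("fewer than two turning points in com_x")
    crossing_times = 0.5 * (tv[flips] + tv[flips + 1])
    return float(2.0 * np.mean(np.diff(crossing_times)))


@dataclass(frozen=True)
class TrajectoryMetrics:
    """Per-step diagnostic series of one simulation."""

    times: np.ndarray
    total_mass: np.ndarray
    com_x: np.ndarray
    mixing_cv: np.ndarray
    homogenization_time: float | None
    axial_variance: np.ndarray | None = None  # at snapshot times only

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.total_mass) == len(self.com_x) == len(self.mixing_cv) == n):
            raise InvalidInputError("metric series lengths differ")


def trajectory_metrics(
    traj: Trajectory, threshold: float = 0.05
) -> TrajectoryMetrics:
    """Assemble the per-step metric series recorded during a simulation.

    The mixing CV uses the ``n_record_segments`` segment means recorded at
    every step; axial variance is computed from the stored snapshots.
    """
    cv = np.array([segment_cv(row) for row in traj.segment_means])
    return TrajectoryMetrics(
        times=traj.times,
        total_mass=traj.total_mass,
        com_x=traj.com_x,
        mixing_cv=cv,
        homogenization_time=homogenization_time(traj.times, cv, threshold),
        axial_variance=np.array([axial_variance(s) for s in traj.snapshots])
        if traj.snapshots
        else None,
    )
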