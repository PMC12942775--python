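"""Domain types for the rocked circulation channel and its tracer model.

All quantities are SI internally (meters, seconds, Pa, kg·m⁻³); unit-suffixed
configuration keys (mm, cycles·min⁻¹, µL·s⁻¹, …) are converted once at the
config boundary (:mod:`mochip.config`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "ChannelGeometry",
    "FluidProperties",
    "RockingProtocol",
    "TracerSpec",
    "Grid",
    "TracerField",
    "InitialCondition",
    "SimulationConfig",
    "NoiseSpec",
    "WATER",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidInputError(msg)


@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular circulation channel (axial length × width × height).

    The 2D transport model lives in the axial × vertical (length × height)
    plane; the width enters only through the hydraulic diagnostics.
    """

    length: float  # m, axial extent (device value 40 mm)
    width: float   # m (device value 4 mm)
    height: float  # m, the short, vertical dimension (device value 2 mm)

    def __post_init__(self) -> None:
        _require(self.length > 0, f"length must be > 0, got {self.length}")
        _require(self.width > 0, f"width must be > 0, got {self.width}")
        _require(self.height > 0, f"height must be > 0, got {self.height}")
        _require(
            self.height <= self.width,
            "height must not exceed width: the 2D axial-vertical model "
            f"assumes the short dimension is vertical (H={self.height}, "
            f"W={self.width})",
        )

    @property
    def cross_section_area(self) -> float:
        """Channel cross-section area W·H in m²."""
        return self.width * self.height


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid properties; defaults are water at ≈20 °C."""

    density: float = 1000.0            # kg·m⁻³
    dynamic_viscosity: float = 1.0e-3  # Pa·s

    def __post_init__(self) -> None:
        _require(self.density > 0, f"density must be > 0, got {self.density}")
        _require(
            self.dynamic_viscosity > 0,
            f"dynamic_viscosity must be > 0, got {self.dynamic_viscosity}",
        )


#: Water at ≈20 °C, the perfusion medium approximation used throughout.
WATER = FluidProperties()


@dataclass(frozen=True)
class RockingProtocol:
    """Sinusoidal gravity-rocking drive of the channel.

    ``peak_mean_velocity`` is the temporal amplitude of the cross-section-mean
    axial velocity.  If the experimentally quoted peak was instead the spatial
    maximum at mid-height, set ``peak_is_spatial_max=True`` and the mean
    amplitude becomes ``peak_mean_velocity / 1.5`` (parabolic profile).

    ``tilt_amplitude`` is recorded metadata only: the platform tilt does not
    enter any equation because the velocity amplitude is taken as measured.
    """

    tilt_amplitude: float = 6.0            # degrees, metadata
    frequency_cpm: float = 10.0            # rocking cycles per minute
    peak_mean_velocity: float = 5.0e-3     # m·s⁻¹
    profile_kind: str = "poiseuille"       # "poiseuille" | "plug"
    phase_offset: float = 0.0              # rad; 0 → flow starts at rest, +x
    peak_is_spatial_max: bool = False

    def __post_init__(self) -> None:
        _require(self.frequency_cpm > 0,
                 f"frequency_cpm must be > 0, got {self.frequency_cpm}")
        _require(self.peak_mean_velocity >= 0,
                 f"peak_mean_velocity must be >= 0, got {self.peak_mean_velocity}")
        _require(self.profile_kind in ("poiseuille", "plug"),
                 f"profile_kind must be 'poiseuille' or 'plug', got {self.profile_kind!r}")

    @property
    def frequency_hz(self) -> float:
        """Rocking frequency in Hz (cycles·min⁻¹ / 60)."""
        return self.frequency_cpm / 60.0

    @property
    def omega(self) -> float:
        """Angular frequency ω = 2πf in rad·s⁻¹."""
        return 2.0 * np.pi * self.frequency_hz

    @property
    def period(self) -> float:
        """Rocking period in seconds (6 s at 10 cycles·min⁻¹)."""
        return 1.0 / self.frequency_hz

    @property
    def mean_velocity_amplitude(self) -> float:
        """Amplitude of the cross-section-mean velocity in m·s⁻¹."""
        if self.peak_is_spatial_max and self.profile_kind == "poiseuille":
            return self.peak_mean_velocity / 1.5
        return self.peak_mean_velocity


@dataclass(frozen=True)
class TracerSpec:
    """Passive tracer: fluorescein sodium in water by default.

    A physical tracer has diffusivity > 0; D = 0 is accepted as a
    verification mode (pure-advection oracles with closed-form solutions).
    """

    diffusivity: float = 4.0e-10  # m²·s⁻¹

    def __post_init__(self) -> None:
        _require(self.diffusivity >= 0,
                 f"diffusivity must be >= 0, got {self.diffusivity}")


@dataclass(frozen=True)
class Grid:
    """Uniform cell-centered grid on the axial × vertical plane.

    x runs along the channel (nx cells over `length`), y over the height
    (ny cells).  Concentration arrays are indexed ``C[j, i]`` = (y_j, x_i).
    """

    nx: int
    ny: int
    dx: float  # m, = length / nx exactly
    dy: float  # m, = height / ny exactly

    def __post_init__(self) -> None:
        _require(self.nx >= 4, f"nx must be >= 4, got {self.nx}")
        _require(self.ny >= 3, f"ny must be >= 3, got {self.ny}")
        _require(self.dx > 0 and self.dy > 0, "dx and dy must be > 0")

    @classmethod
    def for_geometry(cls, geometry: ChannelGeometry, nx: int, ny: int) -> "Grid":
        return cls(nx=nx, ny=ny, dx=geometry.length / nx, dy=geometry.height / ny)

    @property
    def x(self) -> np.ndarray:
        """Cell-center x coordinates, shape (nx,)."""
        return (np.arange(self.nx) + 0.5) * self.dx

    @property
    def y(self) -> np.ndarray:
        """Cell-center y coordinates, shape (ny,)."""
        return (np.arange(self.ny) + 0.5) * self.dy

    @property
    def cell_area(self) -> float:
        return self.dx * self.dy


@dataclass(frozen=True)
class TracerField:
    """Tracer concentration snapshot C(y, x) at one instant."""

    concentration: np.ndarray  # shape (ny, nx), arbitrary units, >= 0
    grid: Grid
    time: float  # s

    def __post_init__(self) -> None:
        c = np.asarray(self.concentration, dtype=float)
        _require(c.shape == (self.grid.ny, self.grid.nx),
                 f"concentration shape {c.shape} does not match grid "
                 f"({self.grid.ny}, {self.grid.nx})")
        object.__setattr__(self, "concentration", c)

    def profile(self) -> np.ndarray:
        """Width-averaged (here: height-averaged) axial profile, shape (nx,).

        Emulates how fluorescence dye images are reduced: intensity is
        proportional to the depth-integrated concentration at each x.
        """
        return self.concentration.mean(axis=0)


@dataclass(frozen=True)
class InitialCondition:
    """Initial tracer distribution.

    kinds:
      - ``centered_block``: concentration 1 in the central ``fraction`` of
        the channel length, uniform over height (default fraction 0.1);
      - ``gaussian``: Gaussian in x centered at ``center`` with std ``sigma``,
        uniform over height;
      - ``left_step``: concentration 1 for x below ``fraction``·length.
    """

    kind: str = "centered_block"
    fraction: float = 0.1
    center: float | None = None  # m; gaussian only, default mid-channel
    sigma: float | None = None   # m; gaussian only

    def __post_init__(self) -> None:
        _require(self.kind in ("centered_block", "gaussian", "left_step"),
                 f"unknown initial-condition kind {self.kind!r}")
        if self.kind in ("centered_block", "left_step"):
            _require(0 < self.fraction <= 1,
                     f"fraction must be in (0, 1], got {self.fraction}")
        if self.kind == "gaussian":
            _require(self.sigma is not None and self.sigma > 0,
                     "gaussian initial condition requires sigma > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Complete specification of one tracer-transport simulation."""

    geometry: ChannelGeometry
    fluid: FluidProperties
    protocol: RockingProtocol
    tracer: TracerSpec
    nx: int = 400
    ny: int = 20
    initial_condition: InitialCondition = field(default_factory=InitialCondition)
    duration: float = 20.0
    snapshot_times: tuple[float, ...] = (0.0, 2.5, 5.0, 7.5, 20.0)
    cfl_number: float = 0.9
    diffusion_number_max: float = 0.25
    advection_scheme: str = "upwind"  # "upwind" | "van_leer"
    n_record_segments: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.duration > 0, f"duration must be > 0, got {self.duration}")
        _require(0 < self.cfl_number <= 1,
                 f"cfl_number must be in (0, 1], got {self.cfl_number}")
        _require(0 < self.diffusion_number_max <= 0.25,
                 "diffusion_number_max must be in (0, 0.25] for the explicit "
                 f"5-point scheme, got {self.diffusion_number_max}")
        _require(self.advection_scheme in ("upwind", "van_leer"),
                 f"unknown advection_scheme {self.advection_scheme!r}")
        _require(self.n_record_segments >= 2,
                 f"n_record_segments must be >= 2, got {self.n_record_segments}")
        ts = tuple(float(t) for t in self.snapshot_times)
        _require(all(b > a for a, b in zip(ts, ts[1:])),
                 "snapshot_times must be strictly ascending")
        _require(not ts or (ts[0] >= 0 and ts[-1] <= self.duration),
                 f"snapshot_times must lie within [0, duration={self.duration}]")
        object.__setattr__(self, "snapshot_times", ts)

    def grid(self) -> Grid:
        return Grid.for_geometry(self.geometry, self.nx, self.ny)

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class NoiseSpec:
    """Minimal camera model for synthetic dye observations.

    Observed intensity = true width-averaged profile
    + ``background_offset``·max_signal + N(0, (``additive_sigma``·max_signal)²)
    where max_signal is the maximum of the noiseless profiles.  The same seed
    always yields identical draws.
    """

    additive_sigma: float = 0.05     # fraction of max signal
    background_offset: float = 0.02  # fraction of max signal
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.additive_sigma >= 0,
                 f"additive_sigma must be >= 0, got {self.additive_sigma}")
        _require(self.background_offset >= 0,
                 f"background_offset must be >= 0, got {self.background_offset}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)
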