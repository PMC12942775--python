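"""Configuration files, unit conversion, and CSV tables.

Config files are TOML (``.toml``) or YAML (``.yaml``/``.yml``).  Every key
carries its unit in its name (``length_mm``, ``flow_rate_ul_s``,
``frequency_cpm``, …) and is converted to SI exactly once, here; the rest of
the package is unit-suffix free and purely SI.  Unknown keys are rejected
with an error naming the key, so typos cannot silently fall back to
defaults.  Omitted sections take the reference-device defaults.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigError, InvalidInputError, MochipError
from .synthetic import make_reference_config
from .types import (
    ChannelGeometry,
    FluidProperties,
    InitialCondition,
    RockingProtocol,
    SimulationConfig,
    TracerSpec,
)

__all__ = [
    "RunConfig",
    "load_config",
    "config_to_dict",
    "dump_config",
    "config_hash",
    "write_table",
    "read_table",
]

MM = 1e-3
UL_S = 1e-9  # µL·s⁻¹ → m³·s⁻¹


@dataclass(frozen=True)
class RunConfig:
    """A simulation config plus the hydraulics operating point."""

    simulation: SimulationConfig
    flow_rate: float    # m³·s⁻¹, steady-equivalent rate for the diagnostics
    path_length: float  # m, pressure-drop path

    def __post_init__(self) -> None:
        if self.flow_rate < 0:
            raise InvalidInputError(f"flow_rate must be >= 0, got {self.flow_rate}")
        if self.path_length <= 0:
            raise InvalidInputError(
                f"path_length must be > 0, got {self.path_length}"
            )


def default_run_config() -> RunConfig:
    """Reference device at its measured operating point."""
    return RunConfig(
        simulation=make_reference_config(),
        flow_rate=44.4 * UL_S,
        path_length=5.55 * MM,
    )


def _section(raw: dict, name: str, allowed: set[str]) -> dict:
    sec = raw.pop(name, {})
    if not isinstance(sec, dict):
        raise ConfigError(f"section '{name}' must be a table/mapping")
    unknown = set(sec) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section '{name}': {', '.join(sorted(unknown))}"
        )
    return sec


def _parse(raw: dict, source: str) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError(f"{source}: top level must be a table/mapping")
    raw = dict(raw)
    ref = make_reference_config()
    try:
        g = _section(raw, "geometry", {"length_mm", "width_mm", "height_mm"})
        geometry = ChannelGeometry(
            length=g.get("length_mm", 40.0) * MM,
            width=g.get("width_mm", 4.0) * MM,
            height=g.get("height_mm", 2.0) * MM,
        )
        f = _section(raw, "fluid", {"density_kg_m3", "viscosity_mpa_s"})
        fluid = FluidProperties(
            density=f.get("density_kg_m3", 1000.0),
            dynamic_viscosity=f.get("viscosity_mpa_s", 1.0) * 1e-3,
        )
        p = _section(
            raw,
            "protocol",
            {
                "tilt_amplitude_deg",
                "frequency_cpm",
                "peak_mean_velocity_mm_s",
                "profile_kind",
                "phase_offset_rad",
                "peak_is_spatial_max",
            },
        )
        protocol = RockingProtocol(
            tilt_amplitude=p.get("tilt_amplitude_deg", 6.0),
            frequency_cpm=p.get("frequency_cpm", 10.0),
            peak_mean_velocity=p.get("peak_mean_velocity_mm_s", 5.0) * MM,
            profile_kind=p.get("profile_kind", "poiseuille"),
            phase_offset=p.get("phase_offset_rad", 0.0),
            peak_is_spatial_max=p.get("peak_is_spatial_max", False),
        )
        tr = _section(raw, "tracer", {"diffusivity_m2_s"})
        tracer = TracerSpec(diffusivity=tr.get("diffusivity_m2_s", 4e-10))

        s = _section(
            raw,
            "simulation",
            {
                "nx",
                "ny",
                "duration_s",
                "snapshot_times_s",
                "cfl_number",
                "diffusion_number_max",
                "advection_scheme",
                "n_record_segments",
                "seed",
                "initial_condition",
            },
        )
        ic_raw = s.pop("initial_condition", {})
        if not isinstance(ic_raw, dict):
            raise ConfigError("'simulation.initial_condition' must be a mapping")
        unknown = set(ic_raw) - {"kind", "fraction", "center_mm", "sigma_mm"}
        if unknown:
            raise ConfigError(
                "unknown key(s) in 'simulation.initial_condition': "
                + ", ".join(sorted(unknown))
            )
        ic = InitialCondition(
            kind=ic_raw.get("kind", "centered_block"),
            fraction=ic_raw.get("fraction", 0.1),
            center=None
            if ic_raw.get("center_mm") is None
            else ic_raw["center_mm"] * MM,
            sigma=None
            if ic_raw.get("sigma_mm") is None
            else ic_raw["sigma_mm"] * MM,
        )
        simulation = SimulationConfig(
            geometry=geometry,
            fluid=fluid,
            protocol=protocol,
            tracer=tracer,
            nx=s.get("nx", ref.nx),
            ny=s.get("ny", ref.ny),
            initial_condition=ic,
            duration=s.get("duration_s", ref.duration),
            snapshot_times=tuple(s.get("snapshot_times_s", ref.snapshot_times)),
            cfl_number=s.get("cfl_number", ref.cfl_number),
            diffusion_number_max=s.get("diffusion_number_max", ref.diffusion_number_max),
            advection_scheme=s.get("advection_scheme", ref.advection_scheme),
            n_record_segments=s.get("n_record_segments", ref.n_record_segments),
            seed=s.get("seed", ref.seed),
        )
        h = _section(raw, "hydraulics", {"flow_rate_ul_s", "path_length_mm"})
        run = RunConfig(
            simulation=simulation,
            flow_rate=h.get("flow_rate_ul_s", 44.4) * UL_S,
            path_length=h.get("path_length_mm", 5.55) * MM,
        )
    except ConfigError:
        raise
    except MochipError as exc:
        raise ConfigError(f"{source}: {exc}") from exc
    if raw:
        raise ConfigError(
            f"{source}: unknown section(s): {', '.join(sorted(raw))}"
        )
    return run


def load_config(path) -> RunConfig:
    """Read, validate, and unit-convert a TOML or YAML configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    if path.suffix == ".toml":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    elif path.suffix in (".yaml", ".yml"):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raise ConfigError(
            f"unsupported config format {path.suffix!r} (use .toml/.yaml/.yml)"
        )
    return _parse(raw, str(path))


def config_to_dict(run: RunConfig) -> dict:
    """Inverse of :func:`load_config`: RunConfig → unit-suffixed plain dict."""
    sim = run.simulation
    ic = sim.initial_condition
    ic_d: dict = {"kind": ic.kind, "fraction": ic.fraction}
    if ic.center is not None:
        ic_d["center_mm"] = ic.center / MM
    if ic.sigma is not None:
        ic_d["sigma_mm"] = ic.sigma / MM
    return {
        "geometry": {
            "length_mm": sim.geometry.length / MM,
            "width_mm": sim.geometry.width / MM,
            "height_mm": sim.geometry.height / MM,
        },
        "fluid": {
            "density_kg_m3": sim.fluid.density,
            "viscosity_mpa_s": sim.fluid.dynamic_viscosity * 1e3,
        },
        "protocol": {
            "tilt_amplitude_deg": sim.protocol.tilt_amplitude,
            "frequency_cpm": sim.protocol.frequency_cpm,
            "peak_mean_velocity_mm_s": sim.protocol.peak_mean_velocity / MM,
            "profile_kind": sim.protocol.profile_kind,
            "phase_offset_rad": sim.protocol.phase_offset,
            "peak_is_spatial_max": sim.protocol.peak_is_spatial_max,
        },
        "tracer": {"diffusivity_m2_s": sim.tracer.diffusivity},
        "simulation": {
            "nx": sim.nx,
            "ny": sim.ny,
            "duration_s": sim.duration,
            "snapshot_times_s": list(sim.snapshot_times),
            "cfl_number": sim.cfl_number,
            "diffusion_number_max": sim.diffusion_number_max,
            "advection_scheme": sim.advection_scheme,
            "n_record_segments": sim.n_record_segments,
            "seed": sim.seed,
            "initial_condition": ic_d,
        },
        "hydraulics": {
            "flow_rate_ul_s": run.flow_rate / UL_S,
            "path_length_mm": run.path_length / MM,
        },
    }


def dump_config(run: RunConfig, path) -> Path:
    """Write a RunConfig as YAML; ``load_config`` round-trips it exactly."""
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(run), fh, sort_keys=False)
    return path


def config_hash(run: RunConfig) -> str:
    """SHA-256 of the canonical JSON form; stable under key reordering."""
    payload = json.dumps(config_to_dict(run), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def write_table(frame: pd.DataFrame, path) -> Path:
    """Write a DataFrame as RFC-4180 CSV at 12 significant digits."""
    path = Path(path)
    try:
        frame.to_csv(path, index=False, float_format="%.12g")
    except OSError as exc:
        raise MochipError(f"cannot write table {path}: {exc}") from exc
    return path


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path)
    except OSError as exc:
        raise MochipError(f"cannot read table {path}: {exc}") from exc
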