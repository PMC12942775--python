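"""Analytic laminar-flow diagnostics for the rectangular circulation channel.

The channel (40 mm × 4 mm × 2 mm for the reference device) is shallow and
wide, so wall shear stress and pressure drop use the plane-Poiseuille
(infinite parallel-plate) laminar expressions

    τ_w = 6 µ Q / (w h²),        ΔP = 12 µ L Q / (w h³),

which at Q = 44.4 µL·s⁻¹ in water give the gentle-shear operating point of
the device (τ ≈ 0.167 dyn·cm⁻², ΔP ≈ 0.0925 Pa over 5.55 mm, Re ≈ 14.8).
Exact rectangular-duct series solutions are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .types import ChannelGeometry, FluidProperties, RockingProtocol, TracerSpec

__all__ = [
    "hydraulic_diameter",
    "mean_velocity_from_flow_rate",
    "flow_rate_from_mean_velocity",
    "reynolds_number",
    "wall_shear_stress",
    "pa_to_dyn_cm2",
    "pressure_drop",
    "peclet_number",
    "womersley_number",
    "FlowSummary",
    "summarize",
    "LAMINAR_REYNOLDS_MAX",
    "GENTLE_SHEAR_MAX_PA",
]

#: Re below this is flagged laminar (classical transition threshold).
LAMINAR_REYNOLDS_MAX = 2000.0
#: Wall shear at or below this (0.2 dyn·cm⁻²) is flagged gentle-shear.
GENTLE_SHEAR_MAX_PA = 0.02


def hydraulic_diameter(geometry: ChannelGeometry) -> float:
    """D_h = 4·A / P = 2wh/(w+h) for a rectangular duct, in meters.

    Tends to 2h in the wide parallel-plate limit and to the side length for
    a square duct.
    """
    w, h = geometry.width, geometry.height
    return 4.0 * (w * h) / (2.0 * (w + h))


def mean_velocity_from_flow_rate(geometry: ChannelGeometry, flow_rate: float) -> float:
    """Cross-section-mean velocity v̄ = Q / (w·h) in m·s⁻¹."""
    if flow_rate < 0:
        raise InvalidInputError(f"flow_rate must be >= 0, got {flow_rate}")
    return flow_rate / geometry.cross_section_area


def flow_rate_from_mean_velocity(geometry: ChannelGeometry, mean_velocity: float) -> float:
    """Inverse of :func:`mean_velocity_from_flow_rate`; exact round-trip."""
    if mean_velocity < 0:
        raise InvalidInputError(f"mean_velocity must be >= 0, got {mean_velocity}")
    return mean_velocity * geometry.cross_section_area


def reynolds_number(
    geometry: ChannelGeometry, fluid: FluidProperties, mean_velocity: float
) -> float:
    """Re = ρ v̄ D_h / µ on the hydraulic diameter."""
    if mean_velocity < 0:
        raise InvalidInputError(f"mean_velocity must be >= 0, got {mean_velocity}")
    return (
        fluid.density * mean_velocity * hydraulic_diameter(geometry)
        / fluid.dynamic_viscosity
    )


def wall_shear_stress(
    geometry: ChannelGeometry, fluid: FluidProperties, flow_rate: float
) -> float:
    """Wall shear stress τ = 6µQ/(wh²) in Pa (plane-Poiseuille walls)."""
    if flow_rate < 0:
        raise InvalidInputError(f"flow_rate must be >= 0, got {flow_rate}")
    w, h = geometry.width, geometry.height
    return 6.0 * fluid.dynamic_viscosity * flow_rate / (w * h * h)


def pa_to_dyn_cm2(stress_pa: float) -> float:
    """Convert a stress from Pa to dyn·cm⁻² (1 Pa = 10 dyn·cm⁻²)."""
    return 10.0 * stress_pa


def pressure_drop(
    geometry: ChannelGeometry,
    fluid: FluidProperties,
    flow_rate: float,
    path_length: float,
) -> float:
    """Laminar pressure drop ΔP = 12µLQ/(wh³) in Pa over ``path_length``."""
    if flow_rate < 0:
        raise InvalidInputError(f"flow_rate must be >= 0, got {flow_rate}")
    if path_length <= 0:
        raise InvalidInputError(f"path_length must be > 0, got {path_length}")
    w, h = geometry.width, geometry.height
    return 12.0 * fluid.dynamic_viscosity * path_length * flow_rate / (w * h**3)


def peclet_number(peak_velocity: float, height: float, diffusivity: float) -> float:
    """Pe = V·H/D — advective vs diffusive tracer transport across the height.

    Pe ≫ 1 (≈2.5×10⁴ for fluorescein at the device operating point) means
    tracer motion is advection-dominated over a rocking cycle.
    """
    if diffusivity <= 0:
        raise InvalidInputError(f"diffusivity must be > 0, got {diffusivity}")
    if peak_velocity < 0:
        raise InvalidInputError(f"peak_velocity must be >= 0, got {peak_velocity}")
    if height <= 0:
        raise InvalidInputError(f"height must be > 0, got {height}")
    return peak_velocity * height / diffusivity


def womersley_number(
    height: float, fluid: FluidProperties, frequency_cpm: float
) -> float:
    """Wo = (H/2)·sqrt(ωρ/µ) with ω = 2πf, f in Hz.

    Wo ≲ 1 (≈1.02 at 10 cycles·min⁻¹ in the 2 mm channel) justifies the
    quasi-steady parabolic profile used by the transport model.
    """
    if height <= 0:
        raise InvalidInputError(f"height must be > 0, got {height}")
    if frequency_cpm < 0:
        raise InvalidInputError(f"frequency_cpm must be >= 0, got {frequency_cpm}")
    omega = 2.0 * np.pi * frequency_cpm / 60.0
    return (height / 2.0) * np.sqrt(omega * fluid.density / fluid.dynamic_viscosity)


@dataclass(frozen=True)
class FlowSummary:
    """Derived hydraulic diagnostics of one operating point (all SI)."""

    hydraulic_diameter: float   # m
    flow_rate: float            # m³·s⁻¹
    mean_velocity: float        # m·s⁻¹
    reynolds: float
    wall_shear_stress: float    # Pa
    pressure_drop: float        # Pa, over path_length
    path_length: float          # m
    peclet: float
    womersley: float
    laminar: bool
    gentle_shear: bool

    @property
    def wall_shear_stress_dyn_cm2(self) -> float:
        return pa_to_dyn_cm2(self.wall_shear_stress)

    def as_dict(self) -> dict[str, float | bool]:
        return {
            "hydraulic_diameter_m": self.hydraulic_diameter,
            "flow_rate_m3_s": self.flow_rate,
            "mean_velocity_m_s": self.mean_velocity,
            "reynolds": self.reynolds,
            "wall_shear_stress_pa": self.wall_shear_stress,
            "wall_shear_stress_dyn_cm2": self.wall_shear_stress_dyn_cm2,
            "pressure_drop_pa": self.pressure_drop,
            "path_length_m": self.path_length,
            "peclet": self.peclet,
            "womersley": self.womersley,
            "laminar": self.laminar,
            "gentle_shear": self.gentle_shear,
        }


def summarize(
    geometry: ChannelGeometry,
    fluid: FluidProperties,
    protocol: RockingProtocol,
    tracer: TracerSpec,
    flow_rate: float,
    path_length: float,
    laminar_reynolds_max: float = LAMINAR_REYNOLDS_MAX,
    gentle_shear_max_pa: float = GENTLE_SHEAR_MAX_PA,
) -> FlowSummary:
    """Assemble every hydraulic diagnostic for one operating point.

    ``flow_rate`` is the steady-equivalent volumetric rate used for the
    shear/pressure/Reynolds diagnostics; the oscillatory drive enters only
    through the Péclet (via the protocol's peak velocity) and Womersley
    (via its frequency) numbers.
    """
    v_bar = mean_velocity_from_flow_rate(geometry, flow_rate)
    re = reynolds_number(geometry, fluid, v_bar)
    tau = wall_shear_stress(geometry, fluid, flow_rate)
    return FlowSummary(
        hydraulic_diameter=hydraulic_diameter(geometry),
        flow_rate=flow_rate,
        mean_velocity=v_bar,
        reynolds=re,
        wall_shear_stress=tau,
        pressure_drop=pressure_drop(geometry, fluid, flow_rate, path_length),
        path_length=path_length,
        peclet=peclet_number(
            protocol.peak_mean_velocity, geometry.height, tracer.diffusivity
        ),
        womersley=womersley_number(geometry.height, fluid, protocol.frequency_cpm),
        laminar=re < laminar_reynolds_max,
        gentle_shear=tau <= gentle_shear_max_pa,
    )
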