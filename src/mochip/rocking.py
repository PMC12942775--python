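"""Prescribed axial velocity field of the gravity-rocked channel.

The rocker tilts the device sinusoidally, so the cross-section-mean axial
velocity oscillates as V(t) = V_peak·sin(ωt + φ).  Because the Womersley
number is ≈1, the instantaneous profile is quasi-steady: plane Poiseuille
u(y, t) = 6·V(t)·(y/H)(1 − y/H), which is zero at both walls, peaks at
1.5·V(t) at mid-height, and height-averages exactly to V(t).  A uniform
"plug" profile is also provided as a verification mode with an exact
center-of-mass oracle.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError
from .types import ChannelGeometry, RockingProtocol

__all__ = ["mean_velocity", "velocity_profile", "displacement"]


def mean_velocity(t, protocol: RockingProtocol):
    """Cross-section-mean axial velocity V(t) = V_peak·sin(ωt + φ), m·s⁻¹.

    Accepts scalar or array ``t`` (seconds, >= 0).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("t must be >= 0")
    v = protocol.mean_velocity_amplitude * np.sin(
        protocol.omega * t + protocol.phase_offset
    )
    return v if v.ndim else float(v)


def velocity_profile(y, t: float, geometry: ChannelGeometry, protocol: RockingProtocol):
    """Axial velocity u(y, t) at height(s) ``y`` ∈ [0, H], m·s⁻¹.

    Poiseuille: u = 6·V(t)·s(1−s) with s = y/H (no-slip walls); plug: u = V(t).
    """
    y = np.asarray(y, dtype=float)
    h = geometry.height
    if np.any(y < 0) or np.any(y > h):
        raise InvalidInputError(f"y must lie in [0, {h}]")
    v = mean_velocity(t, protocol)
    if protocol.profile_kind == "plug":
        u = np.full_like(y, v, dtype=float)
    else:
        s = y / h
        u = 6.0 * v * s * (1.0 - s)
    return u if u.ndim else float(u)


def displacement(t, protocol: RockingProtocol):
    """Closed-form fluid displacement x(t) = ∫₀ᵗ V dt′, meters.

    For the default phase (flow starting from rest in +x),
    x(t) = (V_peak/ω)(1 − cos ωt): it oscillates between 0 and 2V_peak/ω and
    returns to 0 at every full rocking period.  This is the exact
    center-of-mass trajectory of any tracer blob under plug flow with no
    diffusion, and of a height-uniform blob under the parabolic profile.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("t must be >= 0")
    w = protocol.omega
    phi = protocol.phase_offset
    amp = protocol.mean_velocity_amplitude
    x = (amp / w) * (np.cos(phi) - np.cos(w * t + phi))
    return x if x.ndim else float(x)
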