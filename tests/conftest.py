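import numpy as np
import pytest

import mochip as m


@pytest.fixture(scope="session")
def geometry():
    return m.ChannelGeometry(length=40e-3, width=4e-3, height=2e-3)


@pytest.fixture(scope="session")
def water():
    return m.WATER


@pytest.fixture(scope="session")
def reference_config():
    return m.make_reference_config()


@pytest.fixture(scope="session")
def reference_trajectory(reference_config):
    """The full 20 s reference-device simulation (shared; ~0.5 s)."""
    return m.simulate(reference_config)


@pytest.fixture(scope="session")
def plug_no_diffusion_config(reference_config):
    """Plug flow, zero diffusivity: the exact center-of-mass oracle regime."""
    return reference_config.with_(
        protocol=m.RockingProtocol(profile_kind="plug"),
        tracer=m.TracerSpec(diffusivity=0.0),
        snapshot_times=(0.0, 2.5, 5.0, 6.0, 7.5, 12.0, 20.0),
    )


@pytest.fixture(scope="session")
def diffusion_config(reference_config):
    """No flow, synthetic D = 1e-6 m²/s, Gaussian blob: analytic variance
    growth σ²(t) = σ₀² + 2Dt.  Coarse grid for unit tests (fast)."""
    return reference_config.with_(
        protocol=m.RockingProtocol(peak_mean_velocity=0.0),
        tracer=m.TracerSpec(diffusivity=1e-6),
        nx=200,
        ny=10,
        initial_condition=m.InitialCondition(kind="gaussian", sigma=1.5e-3),
        duration=2.0,
        snapshot_times=tuple(np.linspace(0.0, 2.0, 6)),
    )


@pytest.fixture(scope="session")
def diffusion_trajectory(diffusion_config):
    return m.simulate(diffusion_config)
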