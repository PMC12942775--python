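"""Synthetic dye observations and parameter recovery."""

import numpy as np
import pytest

import mochip as m
from mochip.synthetic import (
    ObservationSet,
    estimate_background,
    make_reference_config,
    recover_diffusivity,
    recover_velocity_amplitude,
    synthesize_observations,
)


class TestReferenceConfig:
    def test_device_parameter_values(self):
        cfg = make_reference_config()
        assert (cfg.geometry.length, cfg.geometry.width, cfg.geometry.height) == (
            40e-3, 4e-3, 2e-3,
        )
        assert cfg.protocol.frequency_cpm == 10.0
        assert cfg.protocol.peak_mean_velocity == 5e-3
        assert cfg.protocol.tilt_amplitude == 6.0
        assert cfg.tracer.diffusivity == 4e-10
        assert cfg.snapshot_times == (0.0, 2.5, 5.0, 7.5, 20.0)


@pytest.fixture(scope="module")
def plug_config():
    return (
        make_reference_config()
        .with_(
            protocol=m.RockingProtocol(profile_kind="plug"),
            tracer=m.TracerSpec(diffusivity=0.0),
            duration=12.0,
            snapshot_times=tuple(np.linspace(0.0, 12.0, 25)),
        )
    )


@pytest.fixture(scope="module")
def plug_trajectory(plug_config):
    return m.simulate(plug_config)


class TestSynthesizeObservations:
    def test_noiseless_equals_simulated_profiles(self, plug_config, plug_trajectory):
        obs = synthesize_observations(
            plug_config, m.NoiseSpec(0.0, 0.0, 0), plug_config.snapshot_times,
            trajectory=plug_trajectory,
        )
        clean = np.stack([s.profile() for s in plug_trajectory.snapshots])
        assert np.array_equal(obs.profiles, clean)

    def test_same_seed_reproduces_identically(self, plug_config, plug_trajectory):
        spec = m.NoiseSpec(0.05, 0.02, 42)
        a = synthesize_observations(
            plug_config, spec, plug_config.snapshot_times, trajectory=plug_trajectory
        )
        b = synthesize_observations(
            plug_config, spec, plug_config.snapshot_times, trajectory=plug_trajectory
        )
        assert np.array_equal(a.profiles, b.profiles)
        assert np.array_equal(a.com_x, b.com_x)

    def test_doubling_sigma_doubles_observed_com_scatter(
        self, plug_config, plug_trajectory
    ):
        # Gaussian scaling of the com perturbation, checked by Monte Carlo
        # over 200 seeded replicates per noise level
        times = plug_config.snapshot_times
        clean = synthesize_observations(
            plug_config, m.NoiseSpec(0.0, 0.0, 0), times, trajectory=plug_trajectory
        ).com_x

        def com_scatter(sigma):
            devs = []
            for seed in range(200):
                obs = synthesize_observations(
                    plug_config,
                    m.NoiseSpec(sigma, 0.02, seed),
                    times,
                    trajectory=plug_trajectory,
                )
                devs.append(obs.com_x - clean)
            return np.std(np.concatenate(devs))

        ratio = com_scatter(0.04) / com_scatter(0.02)
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_rejects_times_outside_duration(self, plug_config):
        with pytest.raises(m.InvalidInputError):
            synthesize_observations(
                plug_config, m.NoiseSpec(), [0.0, plug_config.duration + 1.0]
            )

    def test_background_estimate_recovers_offset(self, plug_config, plug_trajectory):
        obs = synthesize_observations(
            plug_config, m.NoiseSpec(0.0, 0.02, 0), plug_config.snapshot_times,
            trajectory=plug_trajectory,
        )
        # max signal of the plug run is 1.0, so the offset is 0.02 exactly
        assert estimate_background(obs.profiles) == pytest.approx(0.02, abs=1e-9)


class TestRecoverVelocityAmplitude:
    def test_noiseless_plug_flow_within_discretization(
        self, plug_config, plug_trajectory
    ):
        obs = synthesize_observations(
            plug_config, m.NoiseSpec(0.0, 0.0, 0), plug_config.snapshot_times,
            trajectory=plug_trajectory,
        )
        fit = recover_velocity_amplitude(obs, 10.0)
        assert fit.v_peak == pytest.approx(5e-3, rel=0.01)
        assert fit.residual_rms < plug_trajectory.grid.dx

    def test_zero_velocity_recovers_zero_within_noise_floor(self):
        cfg = make_reference_config().with_(
            protocol=m.RockingProtocol(peak_mean_velocity=0.0),
            tracer=m.TracerSpec(diffusivity=1e-6),
            nx=200, ny=10,
            initial_condition=m.InitialCondition(kind="gaussian", sigma=1.5e-3),
            duration=12.0,
            snapshot_times=tuple(np.linspace(0.0, 12.0, 13)),
        )
        obs = synthesize_observations(cfg, m.NoiseSpec(0.0, 0.0, 0), cfg.snapshot_times)
        fit = recover_velocity_amplitude(obs, 10.0)
        assert abs(fit.v_peak) < 1e-5  # ≪ the 5 mm/s operating amplitude

    def test_requires_enough_samples_and_span(self, plug_config, plug_trajectory):
        obs = synthesize_observations(
            plug_config, m.NoiseSpec(0.0, 0.0, 0), plug_config.snapshot_times,
            trajectory=plug_trajectory,
        )
        short = ObservationSet(
            times=obs.times[:6], x=obs.x, profiles=obs.profiles[:6],
            com_x=obs.com_x[:6],
        )
        with pytest.raises(m.InvalidInputError):
            recover_velocity_amplitude(short, 10.0)
        squeezed = ObservationSet(
            times=obs.times[:9] / 3.0, x=obs.x, profiles=obs.profiles[:9],
            com_x=obs.com_x[:9],
        )
        with pytest.raises(m.InvalidInputError):
            recover_velocity_amplitude(squeezed, 10.0)

    def test_sampling_only_at_full_periods_is_degenerate(self, plug_config):
        # every sample at the same rocking phase → cos term unidentifiable
        times = np.arange(8) * 6.0
        com = np.full(8, 20e-3)
        prof = np.ones((8, 16))
        obs = ObservationSet(
            times=times, x=np.linspace(0, 40e-3, 16), profiles=prof, com_x=com
        )
        with pytest.raises(m.DegenerateDataError):
            recover_velocity_amplitude(obs, 10.0)


class TestRecoverDiffusivity:
    def test_noiseless_synthetic_run_within_2_percent(
        self, diffusion_config, diffusion_trajectory
    ):
        obs = synthesize_observations(
            diffusion_config, m.NoiseSpec(0.0, 0.0, 0),
            diffusion_config.snapshot_times, trajectory=diffusion_trajectory,
        )
        fit = recover_diffusivity(obs)
        assert fit.diffusivity == pytest.approx(1e-6, rel=0.02)

    def test_estimate_invariant_to_global_intensity_scaling(
        self, diffusion_config, diffusion_trajectory
    ):
        obs = synthesize_observations(
            diffusion_config, m.NoiseSpec(0.02, 0.02, 3),
            diffusion_config.snapshot_times, trajectory=diffusion_trajectory,
        )
        scaled = ObservationSet(
            times=obs.times, x=obs.x, profiles=37.0 * obs.profiles,
            com_x=obs.com_x,
        )
        assert recover_diffusivity(scaled).diffusivity == pytest.approx(
            recover_diffusivity(obs).diffusivity, rel=1e-6
        )

    def test_duplicate_time_points_rejected(self, diffusion_trajectory):
        x = diffusion_trajectory.grid.x
        prof = diffusion_trajectory.snapshots[0].profile()
        with pytest.raises(m.InvalidInputError):
            ObservationSet(
                times=np.array([0.0, 0.0, 1.0]), x=x,
                profiles=np.stack([prof] * 3), com_x=np.full(3, 20e-3),
            )

    def test_shrinking_profiles_give_degenerate_slope(self, diffusion_config):
        # variance decreasing in time cannot come from diffusion
        x = diffusion_config.grid().x
        sigmas = [3e-3, 2e-3, 1e-3]
        prof = np.stack(
            [np.exp(-0.5 * ((x - 20e-3) / s) ** 2) for s in sigmas]
        )
        obs = ObservationSet(
            times=np.array([0.0, 1.0, 2.0]), x=x, profiles=prof,
            com_x=np.full(3, 20e-3),
        )
        with pytest.raises(m.DegenerateDataError):
            recover_diffusivity(obs)
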