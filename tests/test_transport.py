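"""Finite-difference tracer solver: stability, conservation, oracles."""

import numpy as np
import pytest

import mochip as m
from mochip.metrics import center_of_mass_x, total_mass
from mochip.rocking import displacement
from mochip.render import render_snapshots
from mochip.transport import initialize_field, simulate, stable_dt, step


class TestInitializeField:
    def test_centered_block_support(self, reference_config):
        field = initialize_field(reference_config)
        x = field.grid.x
        prof = field.concentration[0]
        inside = (x >= 18e-3) & (x <= 22e-3)
        assert np.all(prof[inside] == 1.0)
        assert np.all(prof[~inside] == 0.0)
        assert np.all(field.concentration == field.concentration[0])  # y-uniform

    def test_narrow_gaussian_concentrates_in_one_column(self, reference_config):
        cfg = reference_config.with_(
            initial_condition=m.InitialCondition(
                kind="gaussian", center=20.05e-3, sigma=1e-5
            )
        )
        field = initialize_field(cfg)
        prof = field.concentration[0]
        assert prof[prof > 1e-12].size == 1  # all mass in one cell column

    def test_left_step(self, reference_config):
        cfg = reference_config.with_(
            initial_condition=m.InitialCondition(kind="left_step", fraction=0.25)
        )
        prof = initialize_field(cfg).concentration[0]
        assert prof[: 100].sum() == 100.0 and prof[100:].sum() == 0.0

    def test_deterministic(self, reference_config):
        a = initialize_field(reference_config).concentration
        b = initialize_field(reference_config).concentration
        assert np.array_equal(a, b)

    def test_rejects_center_outside_domain(self, reference_config):
        cfg = reference_config.with_(
            initial_condition=m.InitialCondition(
                kind="gaussian", center=50e-3, sigma=1e-3
            )
        )
        with pytest.raises(m.InvalidInputError):
            initialize_field(cfg)


class TestStableDt:
    def test_reference_config_is_advection_limited(self, reference_config):
        # cfl·dx/(1.5 V_peak) = 0.9·1e-4/7.5e-3 = 0.012 s
        assert stable_dt(reference_config) == pytest.approx(0.012, rel=1e-12)

    def test_large_diffusivity_switches_to_diffusion_limit(self, reference_config):
        cfg = reference_config.with_(tracer=m.TracerSpec(diffusivity=1e-4))
        g = cfg.grid()
        expected = 0.25 / (1e-4 * (1 / g.dx**2 + 1 / g.dy**2))
        assert stable_dt(cfg) == pytest.approx(expected, rel=1e-12)
        assert stable_dt(cfg) < stable_dt(reference_config)

    def test_halving_dx_halves_advection_limited_dt(self, reference_config):
        cfg = reference_config.with_(nx=800)
        assert stable_dt(cfg) == pytest.approx(
            stable_dt(reference_config) / 2, rel=1e-12
        )

    def test_plug_flow_uses_mean_amplitude(self, reference_config):
        cfg = reference_config.with_(
            protocol=m.RockingProtocol(profile_kind="plug"),
            tracer=m.TracerSpec(diffusivity=0.0),
        )
        assert stable_dt(cfg) == pytest.approx(0.9 * 1e-4 / 5e-3, rel=1e-12)

    def test_no_dynamics_is_an_error(self, reference_config):
        cfg = reference_config.with_(
            protocol=m.RockingProtocol(peak_mean_velocity=0.0),
            tracer=m.TracerSpec(diffusivity=0.0),
        )
        with pytest.raises(m.InvalidInputError):
            stable_dt(cfg)


class TestStep:
    def test_identity_dynamics_leaves_field_unchanged(self, reference_config):
        cfg = reference_config.with_(
            protocol=m.RockingProtocol(peak_mean_velocity=0.0),
            tracer=m.TracerSpec(diffusivity=0.0),
        )
        field = initialize_field(cfg)
        out = step(field, 1.0, cfg)
        assert np.array_equal(out.concentration, field.concentration)

    def test_uniform_field_is_invariant(self, reference_config):
        # under pure diffusion a constant is exactly invariant; under flow
        # the closed (reflecting) channel ends pile/drain the two boundary
        # columns, so advective invariance of a constant holds in the
        # interior — a deliberate consequence of conserving mass in a
        # domain whose reservoirs are not modeled
        field = initialize_field(reference_config)
        uniform = m.TracerField(np.ones_like(field.concentration), field.grid, 0.0)

        no_flow = reference_config.with_(
            protocol=m.RockingProtocol(peak_mean_velocity=0.0)
        )
        out = step(uniform, stable_dt(no_flow), no_flow)
        assert out.concentration == pytest.approx(1.0, rel=1e-12)

        out = step(uniform, stable_dt(reference_config), reference_config)
        # the diffusion sub-step spreads the end-column deficit one column in
        assert out.concentration[:, 2:-2] == pytest.approx(1.0, rel=1e-12)
        assert out.concentration.sum() == pytest.approx(
            uniform.concentration.sum(), rel=1e-12
        )

    def test_single_column_diffuses_symmetrically(self, reference_config):
        # hand evaluation of the 5-point stencil: one off-center column of
        # concentration 1 loses 2·D·dt/dx² and each x-neighbor gains D·dt/dx²
        cfg = reference_config.with_(
            protocol=m.RockingProtocol(peak_mean_velocity=0.0),
            tracer=m.TracerSpec(diffusivity=1e-6),
        )
        field = initialize_field(cfg)
        g = field.grid
        c = np.zeros((g.ny, g.nx))
        c[:, 100] = 1.0
        dt = stable_dt(cfg)
        alpha = 1e-6 * dt / g.dx**2
        out = step(m.TracerField(c, g, 0.0), dt, cfg).concentration
        assert out[:, 99] == pytest.approx(alpha, rel=1e-12)
        assert out[:, 101] == pytest.approx(alpha, rel=1e-12)
        assert out[:, 100] == pytest.approx(1 - 2 * alpha, rel=1e-12)
        assert out.sum() == pytest.approx(c.sum(), rel=1e-13)

    def test_mass_conserved_each_step(self, reference_config):
        field = initialize_field(reference_config)
        dt = stable_dt(reference_config)
        mass0 = total_mass(field)
        for _ in range(25):
            field = step(field, dt, reference_config)
            assert total_mass(field) == pytest.approx(mass0, rel=1e-12)
            assert field.concentration.min() >= 0.0

    def test_rejects_unstable_dt(self, reference_config):
        field = initialize_field(reference_config)
        with pytest.raises(m.StabilityError):
            step(field, 10 * stable_dt(reference_config), reference_config)


class TestSimulate:
    def test_first_snapshot_is_initial_field(self, reference_trajectory, reference_config):
        snap0 = reference_trajectory.snapshots[0]
        assert snap0.time == 0.0
        assert np.array_equal(
            snap0.concentration, initialize_field(reference_config).concentration
        )

    def test_snapshots_land_exactly_on_requested_times(self, reference_trajectory):
        assert reference_trajectory.snapshot_times == (0.0, 2.5, 5.0, 7.5, 20.0)

    def test_deterministic_for_fixed_config(self, reference_config):
        cfg = reference_config.with_(duration=2.5, snapshot_times=(0.0, 2.5))
        a, b = simulate(cfg), simulate(cfg)
        assert np.array_equal(
            a.snapshots[-1].concentration, b.snapshots[-1].concentration
        )
        assert np.array_equal(a.com_x, b.com_x)

    def test_plug_com_matches_closed_form_displacement(
        self, plug_no_diffusion_config
    ):
        traj = simulate(plug_no_diffusion_config)
        proto = plug_no_diffusion_config.protocol
        dx = traj.grid.dx
        for snap in traj.snapshots:
            expected = 20e-3 + displacement(snap.time, proto)
            assert abs(center_of_mass_x(snap) - expected) < dx

    def test_plug_returns_to_start_every_period(self, plug_no_diffusion_config):
        traj = simulate(plug_no_diffusion_config)
        dx = traj.grid.dx
        for t_periodic in (6.0, 12.0):
            k = np.argmin(np.abs(np.array(traj.snapshot_times) - t_periodic))
            assert abs(center_of_mass_x(traj.snapshots[k]) - 20e-3) < dx

    def test_plug_period_field_recurrence_and_limiter_benefit(
        self, plug_no_diffusion_config
    ):
        # after one full period the exact solution equals the initial field;
        # the numerical field differs only by scheme diffusion, and the van
        # Leer limiter must smear strictly less than first-order upwind
        def l1_recurrence(scheme):
            cfg = plug_no_diffusion_config.with_(
                advection_scheme=scheme, duration=6.0, snapshot_times=(0.0, 6.0)
            )
            traj = simulate(cfg)
            c0, c6 = (s.concentration for s in traj.snapshots)
            return np.abs(c6 - c0).sum() / c0.sum()

        err_upwind = l1_recurrence("upwind")
        err_vanleer = l1_recurrence("van_leer")
        assert err_upwind < 1.0   # documented numerical-diffusion caveat
        assert err_vanleer < 0.5 * err_upwind

    def test_positivity_throughout_reference_run(self, reference_trajectory):
        assert min(s.concentration.min() for s in reference_trajectory.snapshots) >= 0


class TestRenderSnapshots:
    def test_one_png_per_snapshot(self, reference_trajectory, tmp_path):
        paths = render_snapshots(reference_trajectory, tmp_path)
        assert len(paths) == 5
        assert all(p.exists() and p.suffix == ".png" for p in paths)

    def test_empty_trajectory_rejected(self, reference_trajectory, tmp_path):
        import dataclasses

        empty = dataclasses.replace(reference_trajectory, snapshots=())
        with pytest.raises(m.InvalidInputError):
            render_snapshots(empty, tmp_path)
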