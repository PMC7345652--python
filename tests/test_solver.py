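"""Shallow-water surrogate: grid, forcing, stepper, conservation, closures."""

import numpy as np
import pytest

from diadflow import (
    EGM2_37C,
    DishGeometry,
    FillSpec,
    ShakerConfig,
    rpm_to_omega,
    stokes_wss_max,
)
from diadflow.solver import (
    CFLError,
    ConfigurationError,
    FlowFieldSeries,
    SamplingError,
    SimulationSettings,
    _Stepper,
    build_grid,
    orbital_forcing,
    simulate,
    wall_shear,
)

from oracles import naive_step


@pytest.fixture
def diad_134_56():
    return DishGeometry.from_mm(134, 56)


class TestGrid:
    def test_construction(self, diad_134_56):
        grid = build_grid(diad_134_56, SimulationSettings(n_r=4, n_theta=8))
        assert grid.n_r * grid.n_theta == 32
        assert grid.r.min() > 0.028 and grid.r.max() < 0.067
        assert grid.r_in == pytest.approx(0.028)

    def test_plain_dish_core(self):
        grid = build_grid(DishGeometry.from_mm(35), SimulationSettings(n_r=8, n_theta=16))
        assert grid.r_in == pytest.approx(1e-3)

    def test_cell_areas_sum_to_annulus(self, diad_134_56):
        grid = build_grid(diad_134_56, SimulationSettings(n_r=6, n_theta=12))
        assert grid.cell_area.sum() == pytest.approx(diad_134_56.area_m2, rel=5e-3)

    def test_minimum_resolution_enforced(self):
        with pytest.raises(ConfigurationError):
            SimulationSettings(n_r=2)
        with pytest.raises(ConfigurationError):
            SimulationSettings(n_theta=4)


class TestForcing:
    def test_phase_zero_points_along_x(self):
        shaker = ShakerConfig.from_rpm(10, 200)
        f = orbital_forcing(shaker, 0.0)
        assert f[0] == pytest.approx(shaker.orbit_radius * shaker.omega**2)
        assert f[1] == pytest.approx(0.0)

    def test_constant_magnitude(self):
        shaker = ShakerConfig.from_rpm(19, 150)
        mags = [np.linalg.norm(orbital_forcing(shaker, t)) for t in np.linspace(0, 1, 17)]
        assert np.ptp(mags) < 1e-12

    def test_no_orbit_no_forcing(self):
        still = ShakerConfig(orbit_diameter=0.0, omega=rpm_to_omega(200))
        assert np.all(orbital_forcing(still, 0.3) == 0.0)


class TestSimulate:
    def test_still_water_preserved_exactly(self, diad_134_56, fluid):
        """With zero forcing the rest state is a machine-precision fixed point."""
        still = ShakerConfig(orbit_diameter=0.0, omega=rpm_to_omega(200))
        s = simulate(
            diad_134_56,
            still,
            fluid,
            FillSpec(height_mm=3),
            SimulationSettings(n_r=8, n_theta=16, total_time=0.7),
        )
        assert np.all(s.u == 0.0)
        assert np.all(s.h == 3e-3)

    def test_stepper_matches_naive_reimplementation(self, diad_134_56, fluid):
        """Vectorized stepper equals a straightforward loop implementation."""
        shaker = ShakerConfig.from_rpm(10, 200)
        settings = SimulationSettings(n_r=6, n_theta=12)
        grid = build_grid(diad_134_56, settings)
        stepper = _Stepper(grid, fluid, shaker, settings)
        rng = np.random.default_rng(7)
        h = 3e-3 * (1 + 0.2 * rng.standard_normal((6, 12)))
        u = 0.05 * rng.standard_normal((6, 12, 2))
        h2, u2 = h.copy(), u.copy()
        t, dt = 0.0, 1e-3
        for _ in range(3):
            h, u = stepper.step(h, u, t, dt)
            h2, u2 = naive_step(h2, u2, t, dt, grid, fluid, shaker, settings)
            t += dt
        assert np.abs(h - h2).max() < 1e-10
        assert np.abs(u - u2).max() < 1e-10

    def test_forced_run_periodic_and_conservative(self, run_cache):
        s = run_cache("134/56", 10, 200, 3, n_r=16, n_theta=32)
        assert s.diagnostics["volume_drift"] < 1e-3
        vols = s.volume()
        assert np.ptp(vols) / vols[0] < 1e-3
        assert s.n_samples >= 20
        assert np.linalg.norm(s.tau, axis=-1).max() > 0.05  # nonzero periodic WSS

    def test_fixed_timestep_mirrors_transient_protocol(self, diad_134_56, fluid):
        """dt = 0.01 s / 4.0 s cap (the reference transient protocol) must be
        rejected as CFL-unstable on this grid rather than silently diverging."""
        shaker = ShakerConfig.from_rpm(10, 200)
        with pytest.raises(CFLError):
            simulate(
                diad_134_56,
                shaker,
                fluid,
                FillSpec(height_mm=3),
                SimulationSettings(n_r=16, n_theta=32, dt=0.01, total_time=4.0),
            )

    def test_shallow_fill_rejected(self, diad_134_56, fluid):
        shaker = ShakerConfig.from_rpm(10, 200)
        with pytest.raises(ConfigurationError):
            simulate(
                diad_134_56,
                shaker,
                fluid,
                FillSpec(height_mm=2e-2),  # 20 µm < 4·h_min
                SimulationSettings(n_r=8, n_theta=16),
            )

    def test_grid_refinement_insensitivity(self, run_cache):
        """Doubling both grid dimensions changes period-mean |τ| by < 10%."""
        coarse = run_cache("134/56", 10, 200, 3, n_r=16, n_theta=32)
        fine = run_cache("134/56", 10, 200, 3, n_r=32, n_theta=64)
        m_c = np.linalg.norm(coarse.tau, axis=-1).mean()
        m_f = np.linalg.norm(fine.tau, axis=-1).mean()
        assert abs(m_f - m_c) / m_c < 0.10

    def test_save_load_roundtrip(self, tmp_path, run_cache):
        s = run_cache("134/56", 10, 200, 3, n_r=16, n_theta=32)
        path = tmp_path / "fields.npz"
        s.save_npz(path)
        loaded = FlowFieldSeries.load_npz(path)
        assert np.array_equal(loaded.h, s.h)
        assert np.array_equal(loaded.u, s.u)
        assert np.array_equal(loaded.tau, s.tau)
        assert loaded.grid.geom.label == "134/56"


class TestWallShear:
    def test_zero_velocity_zero_stress(self, diad_134_56, fluid):
        grid = build_grid(diad_134_56, SimulationSettings(n_r=4, n_theta=8))
        omega = rpm_to_omega(200)
        times = np.arange(20) / 20 * (2 * np.pi / omega)
        u = np.zeros((20, 4, 8, 2))
        s = FlowFieldSeries.from_arrays(grid, times, u, h=3e-3, omega=omega)
        for closure in ("stokes_layer", "lubrication"):
            tau = wall_shear(s, fluid, closure=closure)
            assert np.all(tau == 0.0)

    def test_lubrication_hand_value(self, diad_134_56, fluid):
        """τ = 3μu/h: 0.1 m/s over 3 mm of medium gives 0.07 Pa."""
        grid = build_grid(diad_134_56, SimulationSettings(n_r=4, n_theta=8))
        omega = rpm_to_omega(200)
        times = np.arange(20) / 20 * (2 * np.pi / omega)
        u = np.zeros((20, 4, 8, 2))
        u[..., 0] = 0.1
        s = FlowFieldSeries.from_arrays(grid, times, u, h=3e-3, omega=omega)
        tau = wall_shear(s, fluid, closure="lubrication")
        assert tau[..., 0] == pytest.approx(0.07)
        assert np.all(tau[..., 1] == 0.0)

    def test_stokes_layer_matches_far_field_analytic(self, diad_134_56, fluid):
        """Uniform oscillation of amplitude aω reproduces τ = a√(ρμω³)."""
        shaker = ShakerConfig.from_rpm(10, 200)
        grid = build_grid(diad_134_56, SimulationSettings(n_r=4, n_theta=8))
        n = 40
        times = np.arange(n) / n * shaker.period
        aw = shaker.orbit_radius * shaker.omega
        u = np.zeros((n, 4, 8, 2))
        u[..., 0] = aw * np.sin(shaker.omega * times)[:, None, None]
        u[..., 1] = -aw * np.cos(shaker.omega * times)[:, None, None]
        s = FlowFieldSeries.from_arrays(grid, times, u, h=3e-3, omega=shaker.omega)
        tau = wall_shear(s, fluid, shaker, "stokes_layer")
        peak = np.linalg.norm(tau, axis=-1).max()
        assert peak == pytest.approx(stokes_wss_max(fluid, shaker), rel=1e-6)

    def test_coarse_sampling_rejected(self, diad_134_56, fluid):
        grid = build_grid(diad_134_56, SimulationSettings(n_r=4, n_theta=8))
        omega = rpm_to_omega(200)
        times = np.arange(10) / 10 * (2 * np.pi / omega)
        u = np.zeros((10, 4, 8, 2))
        s = FlowFieldSeries.from_arrays(grid, times, u, h=3e-3, omega=omega)
        with pytest.raises(SamplingError):
            wall_shear(s, fluid, closure="stokes_layer")
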