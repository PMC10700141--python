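import numpy as np
import pytest

from physiodiv.flow import solve_flow
from physiodiv.surface import (
    ErosionParams,
    SurfaceState,
    advance_timestep,
    calibrate,
    diffuse_hillslope,
    effective_slope,
    incision_rate,
    max_stable_dt,
    run_to_equilibrium,
    simulate,
)
from physiodiv.synthetic import TimeSliceForcing, generate_forcing_sequence

from test_flow import cone_island, crater_island


class TestIncisionRate:
    def test_direct_evaluation(self):
        # eps * P^d * (PA)^m * S^n = 4e-7 * 1 * (1e10)^0.5 * 0.01 = 4e-4 m/yr
        r = incision_rate(ErosionParams(), np.array([1.0]), np.array([1e10]),
                          np.array([0.01]))
        assert r[0] == pytest.approx(4e-4, rel=1e-12)

    def test_zero_slope_or_flux_gives_zero(self):
        p = ErosionParams()
        assert incision_rate(p, np.array([1.0]), np.array([1e10]), np.array([0.0]))[0] == 0
        assert incision_rate(p, np.array([1.0]), np.array([0.0]), np.array([0.1]))[0] == 0

    def test_runoff_exponent_law(self):
        p = ErosionParams()
        r1 = incision_rate(p, np.array([1.0]), np.array([1e10]), np.array([0.01]))
        r2 = incision_rate(p, np.array([2.0]), np.array([1e10]), np.array([0.01]))
        assert r2[0] / r1[0] == pytest.approx(2**0.42, rel=1e-12)

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            incision_rate(ErosionParams(), np.array([1.0]), np.array([1.0]),
                          np.array([-0.1]))

    def test_params_must_be_positive(self):
        with pytest.raises(ValueError):
            ErosionParams(kappa=-1.0)


class TestDiffusion:
    def test_constant_elevation_no_increment(self, mesh4):
        dz = diffuse_hillslope(mesh4, np.full(mesh4.n_nodes, 123.0), 0.5, 1e3)
        assert np.allclose(dz, 0.0)

    def test_exact_volume_conservation(self, mesh4):
        rng = np.random.default_rng(2)
        z = rng.normal(0, 1000, mesh4.n_nodes)
        dz = diffuse_hillslope(mesh4, z, 0.5, 1e3)
        total = float((mesh4.cell_area * dz).sum())
        assert abs(total) < 1e-3 * float(np.abs(mesh4.cell_area * dz).sum() + 1)

    def test_cfl_violation_reports_max_stable_dt(self, mesh4):
        kappa = 1e7
        dt_max = max_stable_dt(mesh4, kappa)
        with pytest.raises(ValueError, match="maximum stable"):
            diffuse_hillslope(mesh4, np.zeros(mesh4.n_nodes), kappa, 2 * dt_max)

    def test_gaussian_ridge_matches_heat_kernel(self, mesh5):
        # zonal Gaussian ridge at the equator follows the 1D heat kernel:
        # sigma^2(t) = sigma0^2 + 2*kappa*t, amplitude ~ sigma0/sigma(t)
        lat_arc = mesh5.radius * np.radians(mesh5.node_lonlat[:, 1])
        sig0 = 5e5
        z = np.exp(-lat_arc**2 / (2 * sig0**2))
        kappa, t_total = 1e7, 1.2e4
        n = int(np.ceil(t_total / (0.8 * max_stable_dt(mesh5, kappa))))
        dt = t_total / n
        for _ in range(n):
            z = z + diffuse_hillslope(mesh5, z, kappa, dt)
        s2 = sig0**2 + 2 * kappa * t_total
        analytic = sig0 / np.sqrt(s2) * np.exp(-lat_arc**2 / (2 * s2))
        w = mesh5.cell_area
        l2 = np.sqrt(float((w * (z - analytic) ** 2).sum())
                     / float((w * analytic**2).sum()))
        assert l2 < 0.02


def _forcing(z, runoff, sea_level=0.0):
    return TimeSliceForcing(age=0.0, elevation=z, runoff=runoff, sea_level=sea_level)


class TestAdvanceTimestep:
    def test_island_without_depressions_all_flux_to_ocean(self, mesh4):
        z, _ = cone_island(mesh4)
        runoff = np.where(z > 0, 1.0, 0.0)
        f = _forcing(z, runoff)
        flow = solve_flow(mesh4, z, runoff)
        st = advance_timestep(mesh4, SurfaceState.initial(z), f, flow,
                              ErosionParams(), 5000.0)
        led = st.ledger[-1]
        assert led["endorheic_km3yr"] == 0.0
        assert led["ocean_km3yr"] == pytest.approx(led["erosion_km3yr"], rel=1e-9)
        assert led["erosion_km3yr"] > 0

    def test_crater_traps_all_interior_sediment(self, mesh4):
        # runoff only inside the bowl: every eroded parcel ends in the pit
        z, d = crater_island(mesh4)
        runoff = np.where((d < 10) & (z > 0), 1.0, 0.0)
        f = _forcing(z, runoff)
        flow = solve_flow(mesh4, z, runoff)
        st = advance_timestep(mesh4, SurfaceState.initial(z), f, flow,
                              ErosionParams(), 5000.0)
        led = st.ledger[-1]
        assert led["erosion_km3yr"] > 0
        assert led["ocean_km3yr"] == pytest.approx(0.0, abs=1e-12)
        assert led["endorheic_km3yr"] == pytest.approx(led["erosion_km3yr"], rel=1e-9)
        assert (st.cum_deposition >= 0).all() and (st.cum_erosion >= 0).all()

    def test_ledger_closes_on_every_step_of_a_synthetic_run(self, mesh4):
        f = generate_forcing_sequence(dict(n_slices=1, mesh=mesh4,
                                           depression_count=2), seed=4)[0]
        st = simulate(mesh4, SurfaceState.initial(f.elevation), f,
                      ErosionParams(), dt=5000.0, duration=1e5)
        led = st.ledger_frame()
        assert len(led) == 20
        closure = (led.erosion_km3yr - led.ocean_km3yr - led.endorheic_km3yr).abs()
        assert (closure <= 1e-6 * led.erosion_km3yr).all()


class TestEquilibrium:
    def test_flat_world_zero_uplift_immediately_converged(self, mesh3):
        z = np.zeros(mesh3.n_nodes)
        f = _forcing(z, np.zeros(mesh3.n_nodes), sea_level=-1.0)
        st, trace, conv = run_to_equilibrium(
            mesh3, f, np.zeros(mesh3.n_nodes), ErosionParams(),
            dt=5000.0, max_time=5e4)
        assert conv
        assert trace["erosion_km3yr"].iloc[-1] == 0.0

    def test_uniform_uplift_mean_erosion_matches_uplift(self, mesh3):
        f = generate_forcing_sequence(dict(n_slices=1, mesh=mesh3,
                                           depression_count=0,
                                           orogen_count=1), seed=3)[0]
        f.runoff[:] = 1.0
        f.runoff[f.elevation <= 0] = 0.0
        uplift = np.where(f.elevation > 0, 1e-3, 0.0)
        st, trace, conv = run_to_equilibrium(
            mesh3, f, uplift, ErosionParams(), dt=5000.0, max_time=4e7,
            tol=0.01)
        assert conv
        ero = trace["erosion_km3yr"].iloc[-1]
        up = trace["uplift_km3yr"].iloc[-1]
        assert ero == pytest.approx(up, rel=0.011)

    def test_halving_dt_changes_equilibrium_ocean_flux_little(self, mesh3):
        f = generate_forcing_sequence(dict(n_slices=1, mesh=mesh3,
                                           depression_count=0,
                                           orogen_count=1), seed=6)[0]
        f.runoff[:] = 1.0
        f.runoff[f.elevation <= 0] = 0.0
        uplift = np.where(f.elevation > 0, 1e-3, 0.0)
        flux = {}
        for dt in (5000.0, 2500.0):
            st, trace, conv = run_to_equilibrium(
                mesh3, f, uplift, ErosionParams(), dt=dt, max_time=3e7,
                tol=0.005)
            assert conv
            flux[dt] = st.ledger[-1]["ocean_km3yr"]
        assert abs(flux[2500.0] - flux[5000.0]) / flux[5000.0] < 0.02

    def test_max_time_warning_flag_not_exception(self, mesh3):
        f = generate_forcing_sequence(dict(n_slices=1, mesh=mesh3), seed=2)[0]
        uplift = np.where(f.elevation > 0, 1e-3, 0.0)
        st, trace, conv = run_to_equilibrium(
            mesh3, f, uplift, ErosionParams(), dt=5000.0, max_time=2e4)
        assert conv is False


class TestCalibrate:
    def test_erosion_linear_in_epsilon(self, mesh4):
        f = generate_forcing_sequence(dict(n_slices=1, mesh=mesh4), seed=2)[0]
        flow = solve_flow(mesh4, f.elevation, f.runoff)
        s = effective_slope(flow, f.elevation)
        p1 = ErosionParams()
        p2 = ErosionParams(epsilon=2 * p1.epsilon)
        r1 = incision_rate(p1, f.runoff, flow.water_flux, s)
        r2 = incision_rate(p2, f.runoff, flow.water_flux, s)
        land = ~flow.receivers.is_ocean
        f1 = float((r1 * mesh4.cell_area)[land].sum())
        f2 = float((r2 * mesh4.cell_area)[land].sum())
        assert f2 == pytest.approx(2 * f1, rel=1e-12)

    def test_calibrates_to_modern_mean_erosion_rate(self, mesh4):
        f = generate_forcing_sequence(dict(n_slices=1, mesh=mesh4), seed=2)[0]
        fitted, report = calibrate(mesh4, f, ErosionParams(),
                                   dict(mean_erosion_rate=63.0, density=2.7))
        assert report["mean_erosion_rate_m_per_Myr"] == pytest.approx(63.0, rel=0.02)
        assert fitted.epsilon != ErosionParams().epsilon

    def test_mass_conversion_km3_to_Gt(self, mesh4):
        f = generate_forcing_sequence(dict(n_slices=1, mesh=mesh4), seed=2)[0]
        _, report = calibrate(mesh4, f, ErosionParams(),
                              dict(mean_erosion_rate=63.0, density=2.7))
        assert report["suspended_flux_Gt_yr"] == pytest.approx(
            2.7 * report["ocean_flux_km3_yr"], rel=1e-12)

    def test_unreachable_target_reports_bracket(self, mesh4):
        f = generate_forcing_sequence(dict(n_slices=1, mesh=mesh4), seed=2)[0]
        with pytest.raises(ValueError, match="not bracketed"):
            calibrate(mesh4, f, ErosionParams(),
                      dict(mean_erosion_rate=1e12, density=2.7))
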