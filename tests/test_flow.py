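import numpy as np
import pytest

from rbc_oxyshear.errors import ConfigurationError
from rbc_oxyshear.flow import (
    Channel,
    FlowProblem,
    PulseProfile,
    Tube,
    casson_tube_profile,
    solve_pulsatile,
    solve_steady,
    wall_shear_stress,
)
from rbc_oxyshear.rheology import CassonParams, derive_params


class TestPulseProfile:
    def test_mean_and_periodic_endpoints(self):
        p = PulseProfile()
        assert p.mean == pytest.approx(0.3)
        assert p.velocity(0.0) == pytest.approx(p.velocity(p.period), abs=1e-12)
        assert p.velocity(p.period / 4) == pytest.approx(p.v_max)

    def test_invalid_rejected(self):
        with pytest.raises(ConfigurationError):
            PulseProfile(v_min=0.5, v_max=0.1)


class TestTubeOracle:
    def test_newtonian_limit_matches_poiseuille(self, newtonian_params):
        tw, R = 1.5, 0.003
        prof = casson_tube_profile(tw, R, newtonian_params, n_points=1000)
        mu = newtonian_params.mu0
        exact = tw / (2 * mu * R) * (R**2 - prof.r**2)
        assert np.max(np.abs(prof.u - exact)) / exact.max() < 1e-3

    def test_yield_criterion_no_flow(self):
        p = CassonParams(preset="literal", mu_cap=None)
        d = derive_params(p)
        prof = casson_tube_profile(d.yield_stress, 0.003, p)
        assert prof.no_flow
        assert np.all(prof.u == 0.0)

    def test_plug_region_constant_velocity(self):
        p = CassonParams(preset="literal", mu_cap=None)
        d = derive_params(p)
        tw = 4 * d.yield_stress
        prof = casson_tube_profile(tw, 0.003, p, n_points=4001)
        plug = prof.r < 0.003 * d.yield_stress / tw * 0.999
        assert np.ptp(prof.u[plug]) < 1e-12 * prof.u.max()
        assert np.all(np.diff(prof.u) <= 1e-15)  # monotone, max at the axis

    def test_flow_rate_against_fine_grid_oracle(self):
        p = CassonParams(preset="calibrated")
        coarse = casson_tube_profile(2.0, 0.00315, p, n_points=1000)
        fine = casson_tube_profile(2.0, 0.00315, p, n_points=64001)
        assert coarse.flow_rate == pytest.approx(fine.flow_rate, rel=5e-3)


class TestSolveSteady:
    def test_newtonian_channel_poiseuille_ratio(self, newtonian_params):
        f = solve_steady(FlowProblem(inlet=0.3, rheology=newtonian_params, nx=8, ny=64))
        assert f.u[:, 0].max() / f.v_mean == pytest.approx(1.5, rel=0.01)

    def test_newtonian_tube_poiseuille_ratio(self, newtonian_params):
        f = solve_steady(
            FlowProblem(geometry=Tube(), inlet=0.3, rheology=newtonian_params, nx=8, ny=64)
        )
        assert f.u[:, 0].max() / f.v_mean == pytest.approx(2.0, rel=0.01)

    def test_matches_tube_oracle_at_128_cells(self):
        rheo = CassonParams(preset="calibrated")
        oracle = casson_tube_profile(2.0, 0.00315, rheo, n_points=8001)
        f = solve_steady(
            FlowProblem(geometry=Tube(), inlet=oracle.v_mean, rheology=rheo, nx=8, ny=128)
        )
        ui = np.interp(f.y, oracle.r, oracle.u)
        l2 = np.sqrt(np.mean((f.u[:, 0] - ui) ** 2)) / oracle.u.max()
        assert l2 < 0.01

    def test_grid_convergence_second_order(self):
        rheo = CassonParams(preset="calibrated")
        oracle = casson_tube_profile(2.0, 0.00315, rheo, n_points=16001)
        errs = []
        for ny in (32, 64, 128):
            f = solve_steady(
                FlowProblem(geometry=Tube(), inlet=oracle.v_mean, rheology=rheo, nx=8, ny=ny)
            )
            ui = np.interp(f.y, oracle.r, oracle.u)
            errs.append(np.sqrt(np.mean((f.u[:, 0] - ui) ** 2)))
        assert errs[0] / errs[1] >= 3.0
        assert errs[1] / errs[2] >= 3.0

    def test_zero_inlet_gives_hydrostatic_rest(self):
        f = solve_steady(FlowProblem(inlet=0.0, nx=8, ny=16))
        assert np.all(f.u == 0.0)
        assert np.allclose(f.p, f.p[0, -1])
        assert f.p[0, -1] == pytest.approx(13332.0)

    def test_no_slip_and_divergence_free(self, steady_channel_field):
        f = steady_channel_field
        assert f.u[0, :].max() == 0.0
        assert f.u[-1, :].max() == 0.0
        # developed flow: du/dx = 0 and v = 0 identically
        assert np.all(np.diff(f.u, axis=1) == 0.0)
        assert np.all(f.v == 0.0)

    def test_pressure_decreases_downstream(self, steady_channel_field):
        centerline = steady_channel_field.p[steady_channel_field.p.shape[0] // 2]
        assert np.all(np.diff(centerline) < 0)
        assert centerline[-1] == pytest.approx(13332.0)

    def test_uniform_viscosity_reduces_to_newtonian(self, newtonian_params):
        # cap == floor (below the infinite-shear viscosity, so the cap binds
        # at every shear rate) forces a uniform viscosity; the solution must
        # equal the Newtonian one at that viscosity to near machine precision
        mu = 1.5e-3
        capped = CassonParams(hct=0.4, mu0=1.45e-3, mu_fallback=mu, mu_cap=mu)
        a = solve_steady(FlowProblem(inlet=0.3, rheology=capped, nx=8, ny=32))
        b = solve_steady(
            FlowProblem(inlet=0.3, rheology=CassonParams(hct=1e-12, mu0=mu, mu_cap=None), nx=8, ny=32)
        )
        assert np.max(np.abs(a.u - b.u)) < 1e-10

    def test_pulse_inlet_rejected(self):
        with pytest.raises(ConfigurationError):
            solve_steady(FlowProblem())


class TestWallShearStress:
    def test_plane_poiseuille_closed_form(self, newtonian_params):
        v, h = 0.3, 0.00315
        f = solve_steady(
            FlowProblem(inlet=v, rheology=newtonian_params, nx=8, ny=64)
        )
        wss = wall_shear_stress(f)
        assert wss.wss[0] == pytest.approx(3 * newtonian_params.mu0 * v / h, rel=0.01)

    def test_consistent_with_tube_oracle(self):
        rheo = CassonParams(preset="calibrated")
        oracle = casson_tube_profile(2.0, 0.00315, rheo, n_points=8001)
        f = solve_steady(
            FlowProblem(geometry=Tube(), inlet=oracle.v_mean, rheology=rheo, nx=8, ny=128)
        )
        assert wall_shear_stress(f).wss[0] == pytest.approx(2.0, rel=5e-3)

    def test_zero_flow_zero_wss(self):
        f = solve_steady(FlowProblem(inlet=0.0, nx=8, ny=16))
        assert np.all(wall_shear_stress(f).wss == 0.0)


class TestSolvePulsatile:
    def test_periodicity_and_mean_velocity(self, small_pulsatile_result):
        result, problem = small_pulsatile_result
        assert result.period_change < 1e-3 * problem.inlet.v_max
        assert result.mean_inlet_velocity == pytest.approx(problem.inlet.mean, rel=5e-3)
        # realized per-phase mean velocity tracks the imposed pulse
        for f in result.fields:
            assert f.v_mean == pytest.approx(problem.inlet.velocity(f.time), rel=1e-6)

    def test_mass_conserved_every_phase(self, small_pulsatile_result):
        result, _ = small_pulsatile_result
        for f in result.fields:
            influx = np.trapezoid(f.u[:, 0], f.y)
            outflux = np.trapezoid(f.u[:, -1], f.y)
            assert outflux == pytest.approx(influx, rel=5e-3)

    def test_quasi_steady_limit(self, newtonian_params):
        # at a 50 s period the Womersley number is tiny and each phase must
        # match the steady parabolic profile
        problem = FlowProblem(
            inlet=PulseProfile(period=50.0),
            rheology=newtonian_params,
            nx=8, ny=32, n_store=8,
        )
        result = solve_pulsatile(problem)
        for f in result.fields:
            assert f.u[:, 0].max() / f.v_mean == pytest.approx(1.5, rel=0.02)

    def test_phase_averaged_wss_bracketed_by_steady(self, small_pulsatile_result):
        result, problem = small_pulsatile_result
        mean_wss = np.mean([wall_shear_stress(f).wss[0] for f in result.fields])
        bounds = []
        for v in (problem.inlet.v_min, problem.inlet.v_max):
            fs = solve_steady(
                FlowProblem(geometry=problem.geometry, inlet=v,
                            rheology=problem.rheology, nx=problem.nx, ny=problem.ny)
            )
            bounds.append(wall_shear_stress(fs).wss[0])
        assert bounds[0] <= mean_wss <= bounds[1]

    def test_cfl_violation_rejected(self):
        problem = FlowProblem(dt=1.0)  # grossly violates 0.5*dx/v_max
        with pytest.raises(ConfigurationError):
            solve_pulsatile(problem)

    def test_stored_phases_cover_period(self, small_pulsatile_result):
        result, problem = small_pulsatile_result
        times = [f.time for f in result.fields]
        assert len(times) == problem.n_store
        assert times == sorted(times)
        assert times[0] == pytest.approx(0.0, abs=1e-12)
        assert times[-1] < problem.inlet.period
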