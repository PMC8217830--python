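"""Time stepper: stability bound, update rule, steady states, protocols."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import oxywindow as ow
from oxywindow.solver import (
    _build_operator, _advance, _step_numpy, NUMBA_AVAILABLE,
    InstabilityError, ConvergenceError,
)


def _one_node_grid():
    spec = ow.DomainSpec(Lx=1.0, Ly=1.0, Lz_tissue=2.0, h_pdms=0.0, dx=2.0)
    return ow.build_grid(spec, ow.WindowLayout(()))


class TestStableDt:
    def test_value_at_default_spacing(self, tissue, membrane):
        # 0.9 * 25 / (6 * 3400) with the PDMS diffusivity dominating
        dt = ow.stable_dt(ow.DomainSpec(dx=5.0), tissue, membrane)
        assert dt == pytest.approx(0.9 * 25.0 / (6 * 3400.0))

    def test_value_at_fine_spacing(self, tissue, membrane):
        dt = ow.stable_dt(ow.DomainSpec(Lz_tissue=300, h_pdms=26, dx=2.0), tissue, membrane)
        assert dt == pytest.approx(0.9 * 4.0 / (6 * 3400.0))

    def test_halving_dx_quarters_bound(self, tissue, membrane):
        d1 = ow.stable_dt(ow.DomainSpec(dx=5.0), tissue, membrane)
        d2 = ow.stable_dt(ow.DomainSpec(dx=2.5), tissue, membrane)
        assert d2 == pytest.approx(d1 / 4)


class TestStep:
    def test_equilibrium_is_fixed_point(self, windowless_grid, tissue, membrane):
        state = ow.initial_state(windowless_grid, tissue)
        out = ow.step(state, 1e-3, windowless_grid, tissue, membrane, window_po2=0.0)
        assert np.max(np.abs(out.P - state.P)) < 1e-12

    def test_single_node_closed_form(self, tissue, membrane):
        # zero Laplacian: P+ = dt*K / (1 + dt*K/P0) starting from P=0
        grid = _one_node_grid()
        state = ow.FieldState(np.zeros(grid.shape), 0.0)
        dt = 1e-3
        out = ow.step(state, dt, grid, tissue, membrane, window_po2=0.0)
        expected = (dt * tissue.K) / (1 + dt * tissue.K / tissue.P0)
        assert out.P[0, 0, 0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.029981, abs=1e-6)

    def test_window_nodes_clamped(self, small_grid, tissue, membrane):
        state = ow.initial_state(small_grid, tissue)
        out = ow.step(state, 1e-3, small_grid, tissue, membrane, window_po2=15.2)
        assert np.all(out.P[:, :, 0][small_grid.window_mask] == 15.2)

    @pytest.mark.skipif(not NUMBA_AVAILABLE, reason="compiled kernel not importable")
    def test_numba_matches_numpy_reference(self, small_grid, tissue, membrane):
        op = _build_operator(small_grid, tissue, membrane)
        rng = np.random.default_rng(42)
        P = 30 + 10 * rng.random(small_grid.shape)
        dt = ow.stable_dt(small_grid.spec, tissue, membrane)
        a = _advance(P, op, tissue, dt, 15.2, None, use_numba=True)
        b = _step_numpy(P, op, tissue, dt, 15.2, None)
        assert np.max(np.abs(a - b)) < 1e-12

    def test_homogeneous_column_linear_profile(self, membrane):
        # reaction off, tissue given PDMS properties -> single-material slab
        # with fixed ends must relax to a straight line
        tissue = ow.TissueParams(
            D=membrane.D_prime, k=membrane.k_prime, M0=1e-300, K=1e-300
        )
        spec = ow.DomainSpec(Lx=2.5, Ly=2.5, Lz_tissue=50.0, h_pdms=50.0, dx=5.0)
        layout = ow.WindowLayout(((spec.Lx / 2, spec.Ly / 2, spec.Lx, spec.Ly),))
        grid = ow.build_grid(spec, layout)
        Pa, Pb = 10.0, 40.0
        final, _ = ow.run_to_steady_state(
            ow.initial_state(grid, value=Pb), Pa, grid, tissue, membrane,
            ow.SolverSettings(steady_tol=1e-9, max_time=120.0), top_po2=Pb,
        )
        expected = Pa + (Pb - Pa) * grid.z / grid.z[-1]
        assert np.max(np.abs(final.P[0, 0, :] - expected)) < 1e-6

    def test_unstable_dt_raises(self, small_grid, tissue, membrane):
        state = ow.initial_state(small_grid, tissue)
        bad = 20 * ow.stable_dt(small_grid.spec, tissue, membrane)
        with pytest.raises(InstabilityError):
            ow.run_to_steady_state(
                state, 0.0, small_grid, tissue, membrane,
                ow.SolverSettings(dt=bad, max_time=5.0),
            )


class TestSteadyState:
    def test_windowless_relaxes_to_equilibrium(self, windowless_grid, tissue, membrane):
        final, _ = ow.run_to_steady_state(
            ow.initial_state(windowless_grid, tissue, value=tissue.P0),
            0.0, windowless_grid, tissue, membrane,
            ow.SolverSettings(steady_tol=1e-5, max_time=120.0),
        )
        assert np.max(np.abs(final.P - ow.equilibrium_po2(tissue))) < 0.05

    def test_restart_is_idempotent(self, small_grid, tissue, membrane):
        settings = ow.SolverSettings(max_time=120.0)
        s1, _ = ow.run_to_steady_state(
            ow.initial_state(small_grid, tissue), 15.2, small_grid, tissue, membrane, settings
        )
        s2, settle = ow.run_to_steady_state(s1, 15.2, small_grid, tissue, membrane, settings)
        dt = ow.stable_dt(small_grid.spec, tissue, membrane)
        assert settle <= settings.check_every * dt + 1e-12
        assert np.max(np.abs(s2.P - s1.P)) < 1e-3

    def test_nonconvergence_reports_error(self, small_grid, tissue, membrane):
        with pytest.raises(ConvergenceError):
            ow.run_to_steady_state(
                ow.initial_state(small_grid, tissue), 0.0, small_grid, tissue, membrane,
                ow.SolverSettings(max_time=0.05),
            )

    def test_comparison_principle(self, small_grid, tissue, membrane):
        """Low window PO2 pulls the whole field below equilibrium, high above."""
        eq = ow.equilibrium_po2(tissue)
        settings = ow.SolverSettings(max_time=120.0)
        low, _ = ow.run_to_steady_state(
            ow.initial_state(small_grid, tissue), 15.2, small_grid, tissue, membrane, settings
        )
        assert low.P.max() <= eq + 0.05
        high, _ = ow.run_to_steady_state(
            ow.initial_state(small_grid, tissue), 91.2, small_grid, tissue, membrane, settings
        )
        assert high.P.min() >= eq - 0.05

    def test_monotone_vertical_decay(self, small_grid, tissue, membrane):
        """Under a low challenge the centre-line profile rises monotonically
        with z until it meets the far-field plateau — no spurious wiggles."""
        final, _ = ow.run_to_steady_state(
            ow.initial_state(small_grid, tissue), 15.2, small_grid, tissue, membrane,
            ow.SolverSettings(max_time=120.0),
        )
        ix, iy, _ = small_grid.nearest_index(
            (small_grid.spec.Lx / 2, small_grid.spec.Ly / 2, 0)
        )
        line = final.P[ix, iy, :]
        plateau = np.flatnonzero(line > ow.equilibrium_po2(tissue) - 0.5)
        upto = plateau[0] if plateau.size else len(line) - 1
        assert np.all(np.diff(line[: upto + 1]) > -1e-9)


class TestProtocolRuns:
    def test_uniform_field_tracks_reaction_ode(self, tissue, membrane):
        """A windowless uniform field obeys the scalar reaction ODE; the
        IMEX march converges to the RK oracle at first order in dt."""
        grid = _one_node_grid()
        proto = ow.GasProtocol(((0.5, 0.05), (0.5, 0.12)))
        P_init = 20.0
        sol = solve_ivp(
            lambda t, p: ow.reaction_rate(p, tissue), (0, 1.0), [P_init],
            rtol=1e-11, atol=1e-12, dense_output=True,
        )
        errs = []
        for dt in (4e-4, 2e-4):
            res = ow.run_protocol(
                ow.FieldState(np.full(grid.shape, P_init)), proto,
                [(0.0, 0.0, 0.0)], grid, tissue, membrane,
                ow.SolverSettings(dt=dt), record_dt=0.05,
            )
            exact = sol.sol(res.times)[0]
            errs.append(np.max(np.abs(res.probe_po2[:, 0] - exact)))
        assert errs[0] < 1e-2
        assert errs[0] / errs[1] == pytest.approx(2.0, rel=0.25)

    def test_constant_protocol_matches_steady_run(self, small_grid, tissue, membrane):
        settings = ow.SolverSettings(max_time=120.0)
        steady, _ = ow.run_to_steady_state(
            ow.initial_state(small_grid, tissue), 15.2, small_grid, tissue, membrane, settings
        )
        res = ow.run_protocol(
            ow.initial_state(small_grid, tissue), ow.constant_protocol(0.02, 20.0),
            [(small_grid.spec.Lx / 2, small_grid.spec.Ly / 2, 50.0)],
            small_grid, tissue, membrane, settings,
        )
        ix, iy, iz = small_grid.nearest_index(
            (small_grid.spec.Lx / 2, small_grid.spec.Ly / 2, 50.0)
        )
        assert res.probe_po2[-1, 0] == pytest.approx(steady.P[ix, iy, iz], abs=5e-3)

    def test_segment_edges_are_instantaneous(self, small_grid, tissue, membrane):
        proto = ow.GasProtocol(((0.2, 0.05), (0.2, 0.12)))
        res = ow.run_protocol(
            ow.initial_state(small_grid, ow.TissueParams()), proto, [], small_grid,
            ow.TissueParams(), ow.MembraneParams(), ow.SolverSettings(),
        )
        assert res.segment_edges == (0.2,)
        assert res.times[0] == 0.0
        assert res.times[-1] == pytest.approx(0.4)
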