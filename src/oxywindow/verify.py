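"""Built-in verification: solver vs. independent oracles.

Each check pits the time-marching solver against a reference computed
without its stencil code (closed forms, damped Newton). All run in seconds
on purpose-built small problems; `run_all` powers the CLI `verify`
subcommand and the package's own test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DomainSpec, WindowLayout, build_grid
from .params import TissueParams, MembraneParams, equilibrium_po2
from .solver import (
    SolverSettings, initial_state, run_to_steady_state,
)
from . import oracles


@dataclass(frozen=True)
class CheckResult:
    name: str
    measured: float
    tolerance: float

    @property
    def passed(self) -> bool:
        return self.measured < self.tolerance


def _column_grid(h_pdms: float, Lz_tissue: float, dx: float):
    """1D column: single lateral node, full-footprint window at z=0."""
    spec = DomainSpec(Lx=dx / 2, Ly=dx / 2, Lz_tissue=Lz_tissue, h_pdms=h_pdms, dx=dx)
    layout = WindowLayout(((spec.Lx / 2, spec.Ly / 2, spec.Lx, spec.Ly),))
    return build_grid(spec, layout)


def check_two_layer_profile(dx: float = 2.5, use_numba: bool = True) -> CheckResult:
    """Reaction-free two-layer column, fixed PO2 at both ends, vs. the
    piecewise-linear closed form. Tolerance 1e-4 mmHg."""
    tissue = TissueParams(M0=1e-15, K=1e-12)  # reaction switched off
    membrane = MembraneParams()
    grid = _column_grid(h_pdms=25.0, Lz_tissue=100.0, dx=dx)
    Pa, Pb = 15.2, 41.6
    state = initial_state(grid, value=Pb)
    settings = SolverSettings(steady_tol=1e-7, max_time=600.0, use_numba=use_numba)
    final, _ = run_to_steady_state(
        state, Pa, grid, tissue, membrane, settings, top_po2=Pb
    )
    prob = oracles.SlabProblem(
        layers=(oracles.Layer(25.0, membrane.D_prime, membrane.k_prime),
                oracles.Layer(100.0, tissue.D, tissue.k)),
        P_bottom=Pa, P_top=Pb,
    )
    profile, _ = oracles.two_layer_steady_profile(prob)
    diff = float(np.max(np.abs(final.P[0, 0, :] - profile(grid.z))))
    return CheckResult("two-layer no-reaction profile vs closed form (mmHg)", diff, 1e-4)


def check_linear_consumption(dx: float = 1.25, use_numba: bool = True) -> CheckResult:
    """Pure-tissue column with consumption linearised to alpha*P vs. the
    cosh profile. Tolerance 1e-3 mmHg."""
    alpha = 0.625  # 1/s
    P50_big = 1e6
    tissue = TissueParams(M0=alpha * 3.89e-5 * P50_big, P50=P50_big, K=1e-12)
    membrane = MembraneParams()
    L = 150.0
    grid = _column_grid(h_pdms=0.0, Lz_tissue=L, dx=dx)
    Ps = 30.0
    state = initial_state(grid, value=Ps)
    settings = SolverSettings(steady_tol=1e-7, max_time=600.0, use_numba=use_numba)
    final, _ = run_to_steady_state(state, Ps, grid, tissue, membrane, settings)
    profile = oracles.linear_consumption_profile(Ps, alpha, L, tissue.D)
    diff = float(np.max(np.abs(final.P[0, 0, :] - profile(grid.z))))
    return CheckResult("linear-consumption cosh profile vs closed form (mmHg)", diff, 1e-3)


def check_dense_newton(n: int = 10, use_numba: bool = True) -> CheckResult:
    """Time-marched steady state vs. damped-Newton solution of the full
    nonlinear system on a small 3D grid with a window. Tolerance 1e-3 mmHg."""
    dx = 10.0
    L = (n - 1) * dx
    spec = DomainSpec(Lx=L, Ly=L, Lz_tissue=L - 2 * dx, h_pdms=2 * dx, dx=dx)
    layout = WindowLayout(((L / 2, L / 2, L / 2, L / 3),))
    grid = build_grid(spec, layout)
    tissue, membrane = TissueParams(), MembraneParams()
    pw = 15.2
    marched, _ = run_to_steady_state(
        initial_state(grid, tissue), pw, grid, tissue, membrane,
        SolverSettings(steady_tol=1e-6, max_time=300.0, use_numba=use_numba),
    )
    newton = oracles.dense_steady_solution(grid, tissue, membrane, pw)
    diff = float(np.max(np.abs(marched.P - newton.P)))
    return CheckResult("time-marched vs dense Newton steady state (mmHg)", diff, 1e-3)


def check_far_field_equilibrium(use_numba: bool = True) -> CheckResult:
    """A windowless block must relax to the reaction equilibrium everywhere.
    Tolerance 0.05 mmHg."""
    spec = DomainSpec(Lx=40.0, Ly=40.0, Lz_tissue=60.0, h_pdms=20.0, dx=10.0)
    grid = build_grid(spec, WindowLayout(()))
    tissue = TissueParams()
    final, _ = run_to_steady_state(
        initial_state(grid, tissue, value=tissue.P0), 0.0, grid, tissue,
        MembraneParams(), SolverSettings(steady_tol=1e-5, max_time=300.0, use_numba=use_numba),
    )
    diff = float(np.max(np.abs(final.P - equilibrium_po2(tissue))))
    return CheckResult("windowless block vs reaction equilibrium (mmHg)", diff, 0.05)


def grid_convergence_order(use_numba: bool = True) -> float:
    """Observed convergence order of the 1D linearised-consumption column,
    from errors against the closed form at dx and dx/2."""
    alpha = 0.625
    P50_big = 1e6
    tissue = TissueParams(M0=alpha * 3.89e-5 * P50_big, P50=P50_big, K=1e-12)
    membrane = MembraneParams()
    L, Ps = 150.0, 30.0
    errs = []
    for dx in (10.0, 5.0):
        grid = _column_grid(h_pdms=0.0, Lz_tissue=L, dx=dx)
        final, _ = run_to_steady_state(
            initial_state(grid, value=Ps), Ps, grid, tissue, membrane,
            SolverSettings(steady_tol=1e-8, max_time=900.0, use_numba=use_numba),
        )
        profile = oracles.linear_consumption_profile(Ps, alpha, L, tissue.D)
        errs.append(float(np.max(np.abs(final.P[0, 0, :] - profile(grid.z)))))
    return float(np.log2(errs[0] / errs[1]))


def run_all(use_numba: bool = True) -> list[CheckResult]:
    results = [
        check_two_layer_profile(use_numba=use_numba),
        check_linear_consumption(use_numba=use_numba),
        check_dense_newton(use_numba=use_numba),
        check_far_field_equilibrium(use_numba=use_numba),
    ]
    order = grid_convergence_order(use_numba=use_numba)
    # stored as a deficit so "measured < tolerance" keeps one pass rule
    results.append(CheckResult("grid-convergence order deficit (2 - observed, < 0.3)",
                               2.0 - order, 0.3))
    return results
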