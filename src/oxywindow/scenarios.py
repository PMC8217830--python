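"""Canonical simulation scenarios, packaged end to end.

These wire together the default geometry (single 400 x 200 um window under
25 um of PDMS, tissue block large enough that every reported extent stays
well clear of the zero-flux boundaries), the standard parameters, and the
5% O2 baseline initialisation used by the in vivo protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DomainSpec, build_grid, single_window_layout, SimulationGrid
from .metrics import ExtentCriterion, ExtentReport, extent_report, settle_time
from .params import TissueParams, MembraneParams
from .protocols import percent_to_po2, step_protocol
from .solver import (
    FieldState, SolverSettings, initial_state, run_to_steady_state, run_protocol,
)

#: O2 fractions of the challenge levels
BASELINE_FRACTION = 0.05
LOW_FRACTION = 0.02

#: default probe depths for step-response timing, um from the glass surface
PROBE_DEPTHS_UM = (25.0, 50.0, 75.0, 100.0)


def default_domain(dx: float = 5.0) -> DomainSpec:
    """Production domain: 1200 x 1000 um footprint, 300 um of tissue over a
    25 um membrane. All reported extents stay >= 150 um from every zero-flux
    boundary so the box does not confine the perturbation."""
    return DomainSpec(Lx=1200.0, Ly=1000.0, Lz_tissue=300.0, h_pdms=25.0, dx=dx)


def default_grid(dx: float = 5.0) -> SimulationGrid:
    spec = default_domain(dx)
    return build_grid(spec, single_window_layout(spec, 400.0, 200.0))


@dataclass
class LowO2Result:
    grid: SimulationGrid
    baseline: FieldState          # steady state under the 5% baseline
    challenged: FieldState        # steady state under the 2% challenge
    report: ExtentReport


def low_o2_challenge(
    dx: float = 5.0,
    tissue: TissueParams = TissueParams(),
    membrane: MembraneParams = MembraneParams(),
    settings: SolverSettings | None = None,
    pressure: float = 760.0,
    area_plane_z: float = 75.0,
    criterion: ExtentCriterion = ExtentCriterion(),
) -> LowO2Result:
    """Steady-state low-O2 (2%) challenge from the 5% baseline.

    Returns both steady fields plus the extent report (penetration depth,
    lateral extents, affected area at ``area_plane_z`` um above the glass).
    """
    grid = default_grid(dx)
    settings = settings or SolverSettings(max_time=120.0)
    p5 = percent_to_po2(BASELINE_FRACTION, pressure)
    p2 = percent_to_po2(LOW_FRACTION, pressure)
    baseline, _ = run_to_steady_state(
        initial_state(grid, tissue), p5, grid, tissue, membrane, settings
    )
    challenged, _ = run_to_steady_state(baseline, p2, grid, tissue, membrane, settings)
    report = extent_report(challenged, grid, criterion, area_plane_z)
    return LowO2Result(grid, baseline, challenged, report)


@dataclass
class StepResponseResult:
    grid: SimulationGrid
    times: np.ndarray             # s since the switch
    probe_po2: np.ndarray         # (n_times, n_probes)
    probe_depths_um: tuple[float, ...]
    settle_times_s: tuple[float, ...]

    @property
    def max_settle_time_s(self) -> float:
        return max(self.settle_times_s)


def step_response(
    baseline: FieldState,
    grid: SimulationGrid,
    tissue: TissueParams = TissueParams(),
    membrane: MembraneParams = MembraneParams(),
    settings: SolverSettings | None = None,
    pressure: float = 760.0,
    probe_depths_um: tuple[float, ...] = PROBE_DEPTHS_UM,
    duration: float = 12.0,
    settle_tol: float = 0.1,
) -> StepResponseResult:
    """Instantaneous 5% -> 2% window step from the 5% steady state.

    Probes sit on the vertical line through the window centre at the given
    depths below the glass surface; settle time is the first moment each
    trace stays within ``settle_tol`` mmHg of its final value.
    """
    settings = settings or SolverSettings()
    spec = grid.spec
    cx, cy = spec.Lx / 2, spec.Ly / 2
    probes = [(cx, cy, d) for d in probe_depths_um]
    # a token pre-switch segment so the switch itself is part of the trace
    proto = step_protocol(BASELINE_FRACTION, LOW_FRACTION, 0.1, duration, pressure)
    res = run_protocol(
        baseline, proto, probes, grid, tissue, membrane, settings, record_dt=0.02
    )
    times, vals = res.segment_trace(1, proto)
    settles = tuple(
        settle_time(times, vals[:, i], settle_tol) for i in range(len(probes))
    )
    return StepResponseResult(
        grid=grid, times=times - times[0], probe_po2=vals,
        probe_depths_um=tuple(probe_depths_um), settle_times_s=settles,
    )
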