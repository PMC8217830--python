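"""Semi-implicit time stepping of the two-region oxygen transport PDE.

Tissue region:   dP/dt = D lap(P) + K (1 - P/P0) - (M0/k) P/(P + P50)
Membrane region: dP/dt = D' lap(P)

Discretisation
--------------
Space: second-order central differences on the vertex-centred grid. The
tissue/membrane interface lies exactly on a grid plane, so each vertical
face carries the permeability D*k of the single material it crosses
(classified by the face midpoint), and the flux divergence at a node is
divided by that node's solubility; this imposes continuity of P and of the
dissolved-oxygen flux D*k*dP/dn exactly — the discrete steady state of a
reaction-free two-layer column reproduces the piecewise-linear closed form
to rounding — and reduces to the plain stencil inside either region.
Zero-flux boundaries use mirror ghost values.

Time: an implicit-explicit splitting in which the linear part of the
capillary source, -(K/P0) P, is taken at the new time level (a pointwise
division — the scheme stays matrix-free and fully explicit to evaluate)
while diffusion and the Michaelis-Menten consumption are taken at the old
level:

    P+ = [P + dt (D lap(P) + K - (M0/k) P/(P+P50))] / (1 + dt K/P0).

This damps the stiff linear relaxation toward P0 and is stabler than
forward Euler at the same dt. Window nodes are reset to the chamber PO2
after every step (Dirichlet).

The stability limit is diffusive: dt <= safety * dx^2 / (6 max(D, D')).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import SimulationGrid, DomainSpec
from .params import TissueParams, MembraneParams, equilibrium_po2
from .protocols import GasProtocol

try:  # pragma: no cover - exercised implicitly
    from ._kernels import step_kernel as _numba_step, NUMBA_AVAILABLE
except ImportError:  # pragma: no cover
    NUMBA_AVAILABLE = False
    _numba_step = None


class InstabilityError(RuntimeError):
    """The explicit update produced a negative or non-finite PO2."""


class ConvergenceError(RuntimeError):
    """Steady state was not reached within the allotted simulation time."""


@dataclass(frozen=True)
class SolverSettings:
    """Time-stepping controls.

    dt: step in seconds, or None for the stability bound times
    ``safety_factor``. ``steady_tol`` is the max-norm rate |dP|/dt (mmHg/s)
    below which the field counts as steady; the residual is sampled every
    ``check_every`` steps.
    """

    dt: float | None = None
    safety_factor: float = 0.9
    steady_tol: float = 1e-3
    max_time: float = 60.0
    check_every: int = 25
    use_numba: bool = True

    def __post_init__(self) -> None:
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be > 0 or None for auto")
        if not 0 < self.safety_factor <= 1:
            raise ValueError("safety_factor must be in (0, 1]")
        if self.steady_tol <= 0:
            raise ValueError("steady_tol must be > 0")
        if self.check_every < 1:
            raise ValueError("check_every must be >= 1")


@dataclass
class FieldState:
    """PO2 on every grid node (mmHg) at simulation time t (s)."""

    P: np.ndarray
    t: float = 0.0

    def copy(self) -> "FieldState":
        return FieldState(self.P.copy(), self.t)


def stable_dt(
    spec: DomainSpec,
    tissue: TissueParams = TissueParams(),
    membrane: MembraneParams = MembraneParams(),
    safety_factor: float = 0.9,
) -> float:
    """Largest safe explicit step: safety * dx^2 / (6 max(D, D')) seconds."""
    return safety_factor * spec.dx**2 / (6.0 * max(tissue.D, membrane.D_prime))


def initial_state(
    grid: SimulationGrid, tissue: TissueParams = TissueParams(), value: float | None = None
) -> FieldState:
    """Uniform field at ``value`` mmHg (default: the reaction equilibrium)."""
    if value is None:
        value = equilibrium_po2(tissue)
    return FieldState(np.full(grid.shape, float(value)), 0.0)


# ---------------------------------------------------------------------------
# operator precomputation


@dataclass(frozen=True)
class _Operator:
    """Per-z-level coefficient arrays; materials vary only along z."""

    Dz: np.ndarray      # diffusivity per z-level, um^2/s
    kz: np.ndarray      # solubility per z-level
    wz: np.ndarray      # harmonic-mean permeability D*k on z-faces, len nz-1
    react: np.ndarray   # bool per z-level: reaction terms active (tissue)
    window: np.ndarray  # bool (nx, ny): fixed-PO2 nodes on z=0
    inv_dx2: float


def _build_operator(
    grid: SimulationGrid, tissue: TissueParams, membrane: MembraneParams
) -> _Operator:
    pdms = grid.is_pdms
    Dz = np.where(pdms, membrane.D_prime, tissue.D)
    kz = np.where(pdms, membrane.k_prime, tissue.k)
    # the material interface lies exactly on a grid plane, so every z-face is
    # single-material: classify each face by its midpoint. (A harmonic mean of
    # the adjacent node permeabilities would shift the effective interface
    # half a cell upward and is reserved for faces that genuinely straddle
    # dissimilar materials — none exist on a grid-aligned interface.)
    z_face = (grid.z[:-1] + grid.z[1:]) / 2.0
    face_pdms = z_face < grid.spec.h_pdms
    wz = np.where(
        face_pdms, membrane.D_prime * membrane.k_prime, tissue.D * tissue.k
    )
    return _Operator(
        Dz=Dz, kz=kz, wz=wz, react=~pdms, window=grid.window_mask,
        inv_dx2=1.0 / grid.spec.dx**2,
    )


def _step_numpy(P, op: _Operator, tissue: TissueParams, dt, window_po2, top_po2):
    """Vectorised reference implementation of one time step."""
    nz = P.shape[2]
    # lateral Laplacian with mirror ghosts
    lat = np.zeros_like(P)
    if P.shape[0] > 1:
        px = np.pad(P, ((1, 1), (0, 0), (0, 0)), mode="reflect")
        lat += px[:-2] + px[2:] - 2.0 * P
    if P.shape[1] > 1:
        py = np.pad(P, ((0, 0), (1, 1), (0, 0)), mode="reflect")
        lat += py[:, :-2] + py[:, 2:] - 2.0 * P
    lat *= op.Dz
    vert = np.zeros_like(P)
    if nz > 1:
        wz = op.wz
        dzp = wz * (P[:, :, 1:] - P[:, :, :-1])        # flux up-face, times dx
        vert[:, :, :-1] += dzp
        vert[:, :, 1:] -= dzp
        # mirror ghosts at the two z boundaries
        vert[:, :, 0] += wz[0] * (P[:, :, 1] - P[:, :, 0])
        vert[:, :, -1] += wz[-1] * (P[:, :, -2] - P[:, :, -1])
        vert /= op.kz
    lap = (lat + vert) * op.inv_dx2
    Mk = tissue.consumption_rate
    rate = lap + tissue.K - Mk * P / (P + tissue.P50)
    implicit = 1.0 / (1.0 + dt * tissue.K / tissue.P0)
    Pn = np.where(op.react, (P + dt * rate) * implicit, P + dt * lap)
    Pn[:, :, 0][op.window] = window_po2
    if top_po2 is not None:
        Pn[:, :, -1] = top_po2
    return Pn


def _advance(P, op: _Operator, tissue: TissueParams, dt, window_po2, top_po2, use_numba):
    if use_numba and NUMBA_AVAILABLE:
        Pn = np.empty_like(P)
        _numba_step(
            P, Pn, op.Dz, op.kz, op.wz, op.react, dt, op.inv_dx2,
            tissue.K, tissue.P0, tissue.consumption_rate, tissue.P50,
        )
        Pn[:, :, 0][op.window] = window_po2
        if top_po2 is not None:
            Pn[:, :, -1] = top_po2
        return Pn
    return _step_numpy(P, op, tissue, dt, window_po2, top_po2)


def _check_health(P, t):
    if not np.all(np.isfinite(P)):
        idx = np.unravel_index(int(np.argmin(np.isfinite(P))), P.shape)
        raise InstabilityError(f"non-finite PO2 at node {idx} at t={t:.6g} s")
    mn = P.min()
    if mn < -1e-9:
        idx = np.unravel_index(int(np.argmin(P)), P.shape)
        raise InstabilityError(
            f"negative PO2 {mn:.3g} mmHg at node {idx} at t={t:.6g} s (dt too large?)"
        )


def step(
    state: FieldState,
    dt: float,
    grid: SimulationGrid,
    tissue: TissueParams = TissueParams(),
    membrane: MembraneParams = MembraneParams(),
    window_po2: float = 0.0,
    top_po2: float | None = None,
    use_numba: bool = True,
) -> FieldState:
    """Advance one time step; window nodes end at ``window_po2`` exactly."""
    if window_po2 < 0:
        raise ValueError("window_po2 must be >= 0")
    op = _build_operator(grid, tissue, membrane)
    Pn = _advance(state.P, op, tissue, dt, window_po2, top_po2, use_numba)
    _check_health(Pn, state.t + dt)
    return FieldState(Pn, state.t + dt)


def run_to_steady_state(
    init: FieldState,
    window_po2: float,
    grid: SimulationGrid,
    tissue: TissueParams = TissueParams(),
    membrane: MembraneParams = MembraneParams(),
    settings: SolverSettings = SolverSettings(),
    top_po2: float | None = None,
) -> tuple[FieldState, float]:
    """March until max |dP|/dt < steady_tol; returns (field, settle_time).

    ``settle_time`` is the first sampled time at which the criterion held
    (sampling granularity = check_every steps). Raises ConvergenceError if
    ``max_time`` of simulated time passes first.
    """
    op = _build_operator(grid, tissue, membrane)
    dt = settings.dt if settings.dt is not None else stable_dt(
        grid.spec, tissue, membrane, settings.safety_factor
    )
    P = init.P.copy()
    # clamp the boundary before the first residual measurement
    P[:, :, 0][op.window] = window_po2
    t = 0.0
    n_steps = int(np.ceil(settings.max_time / dt))
    chunk = settings.check_every
    done = 0
    while done < n_steps:
        m = min(chunk, n_steps - done)
        for _ in range(m - 1):
            P = _advance(P, op, tissue, dt, window_po2, top_po2, settings.use_numba)
        Pn = _advance(P, op, tissue, dt, window_po2, top_po2, settings.use_numba)
        resid = float(np.max(np.abs(Pn - P))) / dt
        P = Pn
        done += m
        t = done * dt
        _check_health(P, t)
        if resid < settings.steady_tol:
            return FieldState(P, init.t + t), t
    raise ConvergenceError(
        f"no steady state within max_time={settings.max_time} s "
        f"(residual {resid:.3g} mmHg/s > tol {settings.steady_tol})"
    )


@dataclass
class ProtocolResult:
    """Probe traces and optional field snapshots from a protocol run."""

    times: np.ndarray                 # s, from protocol start
    probe_po2: np.ndarray             # (n_times, n_probes) mmHg
    probe_points: tuple[tuple[float, float, float], ...]
    probe_indices: tuple[tuple[int, int, int], ...]
    segment_edges: tuple[float, ...]
    snapshots: list[tuple[float, FieldState]] = field(default_factory=list)

    def segment_trace(self, i_segment: int, protocol: GasProtocol):
        """(times, values) restricted to one protocol segment."""
        starts = (0.0,) + protocol.edges
        ends = protocol.edges + (protocol.total_duration,)
        m = (self.times >= starts[i_segment] - 1e-12) & (self.times <= ends[i_segment] + 1e-12)
        return self.times[m], self.probe_po2[m]


def run_protocol(
    init: FieldState,
    protocol: GasProtocol,
    probes: list[tuple[float, float, float]],
    grid: SimulationGrid,
    tissue: TissueParams = TissueParams(),
    membrane: MembraneParams = MembraneParams(),
    settings: SolverSettings = SolverSettings(),
    record_dt: float = 0.05,
    snapshot_segment_ends: bool = False,
) -> ProtocolResult:
    """Drive the window PO2 through the protocol's square wave.

    The boundary value switches instantaneously at segment edges (dt is
    shrunk per segment so edges land on step boundaries exactly). Probe PO2
    is recorded at ``record_dt`` cadence at the grid node nearest each probe
    point; full-field snapshots are kept at segment ends on request.
    """
    op = _build_operator(grid, tissue, membrane)
    dt0 = settings.dt if settings.dt is not None else stable_dt(
        grid.spec, tissue, membrane, settings.safety_factor
    )
    idxs = tuple(grid.nearest_index(p) for p in probes)
    P = init.P.copy()
    times, values = [], []
    snapshots: list[tuple[float, FieldState]] = []
    t = 0.0

    def record():
        times.append(t)
        values.append([P[i] for i in idxs])

    for d, frac in protocol.segments:
        pw = protocol.po2_of_fraction(frac)
        n = max(1, int(np.ceil(d / dt0 - 1e-12)))
        dt = d / n
        rec_every = max(1, int(round(record_dt / dt)))
        P[:, :, 0][op.window] = pw  # instantaneous switch
        record()
        for s in range(1, n + 1):
            P = _advance(P, op, tissue, dt, pw, None, settings.use_numba)
            t += dt
            if s % rec_every == 0 or s == n:
                record()
        _check_health(P, t)
        if snapshot_segment_ends:
            snapshots.append((t, FieldState(P.copy(), init.t + t)))
    return ProtocolResult(
        times=np.asarray(times),
        probe_po2=np.asarray(values),
        probe_points=tuple(tuple(p) for p in probes),
        probe_indices=idxs,
        segment_edges=protocol.edges,
        snapshots=snapshots,
    )
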