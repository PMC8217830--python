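"""Independent reference solutions used to validate the time-marching solver.

None of these reuse the solver's stencil code: the 1D profiles are closed
forms and the dense steady solution assembles its own equations node by
node and solves them by damped Newton iteration. Agreement between the two
routes is what justifies trusting the 3D results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .geometry import SimulationGrid
from .params import TissueParams, MembraneParams
from .solver import FieldState


@dataclass(frozen=True)
class Layer:
    """One homogeneous slab: thickness (um), diffusivity D (um^2/s),
    solubility k (mL O2/mL/mmHg)."""

    thickness: float
    D: float
    k: float

    def __post_init__(self) -> None:
        if self.thickness <= 0 or self.D <= 0 or self.k <= 0:
            raise ValueError("layer thickness, D and k must be > 0")


@dataclass(frozen=True)
class SlabProblem:
    """1D multilayer diffusion problem with fixed-PO2 end conditions."""

    layers: tuple[Layer, ...]
    P_bottom: float
    P_top: float


def two_layer_steady_profile(problem: SlabProblem):
    """Closed-form steady profile of a reaction-free two-layer slab.

    Returns ``(profile, P_interface)`` where ``profile(z)`` evaluates the
    piecewise-linear solution (z measured from the bottom face). Flux
    continuity of D*k*dP/dz at the interface determines the kink:
    G1 (Pa - Pi) = G2 (Pi - Pb) with G = D*k / thickness.
    """
    if len(problem.layers) != 2:
        raise ValueError("exactly two layers required")
    (l1, l2) = problem.layers
    Pa, Pb = problem.P_bottom, problem.P_top
    G1 = l1.D * l1.k / l1.thickness
    G2 = l2.D * l2.k / l2.thickness
    Pi = (G1 * Pa + G2 * Pb) / (G1 + G2)
    z1 = l1.thickness

    def profile(z):
        z = np.asarray(z, dtype=float)
        lower = Pa + (Pi - Pa) * z / l1.thickness
        upper = Pi + (Pb - Pi) * (z - z1) / l2.thickness
        out = np.where(z <= z1, lower, upper)
        return out if out.ndim else float(out)

    return profile, float(Pi)


def krogh_slab_depth(Ps: float, tissue: TissueParams = TissueParams()) -> float:
    """Classical zero-order-consumption penetration depth, um.

    For a slab fed at surface PO2 ``Ps`` with constant volumetric
    consumption M0 (the P >> P50 limit, no capillary source), P and dP/dz
    vanish together at depth sqrt(2 D Ps / (M0/k)).
    """
    if Ps < 0:
        raise ValueError("Ps must be >= 0")
    return math.sqrt(2.0 * tissue.D * Ps / tissue.consumption_rate)


def linear_consumption_profile(Ps: float, alpha: float, L: float, D: float):
    """Steady 1D profile under consumption linear in P: D P'' = alpha P.

    Fixed P(0)=Ps, zero flux at z=L. Returns ``profile(z)``:
    P(z) = Ps cosh((L - z)/l) / cosh(L/l) with l = sqrt(D/alpha).
    """
    if alpha <= 0 or L <= 0 or D <= 0:
        raise ValueError("alpha, L and D must be > 0")
    ell = math.sqrt(D / alpha)

    def profile(z):
        z = np.asarray(z, dtype=float)
        out = Ps * np.cosh((L - z) / ell) / math.cosh(L / ell)
        return out if out.ndim else float(out)

    return profile


# ---------------------------------------------------------------------------
# dense nonlinear steady solution (small grids only)

_MAX_NODES = 20**3


def _assemble_diffusion(grid: SimulationGrid, tissue: TissueParams, membrane: MembraneParams):
    """Sparse diffusion operator assembled node by node (independent of the
    solver's vectorised stencil). Mirror ghosts at zero-flux boundaries,
    single-material permeability on z-faces, Dirichlet rows for window nodes."""
    nx, ny, nz = grid.shape
    dx2 = grid.spec.dx**2
    Dn = np.where(grid.is_pdms, membrane.D_prime, tissue.D)
    kn = np.where(grid.is_pdms, membrane.k_prime, tissue.k)
    # permeability of each z-face, classified by the face midpoint material
    face_perm = np.where(
        (grid.z[:-1] + grid.z[1:]) / 2.0 < grid.spec.h_pdms,
        membrane.D_prime * membrane.k_prime,
        tissue.D * tissue.k,
    )

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    rows, cols, vals = [], [], []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                n = nid(i, j, k)
                if k == 0 and grid.window_mask[i, j]:
                    continue  # Dirichlet row handled by caller
                # lateral neighbours (mirror at boundaries), same material
                for ii, jj in ((i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
                    im = ii
                    jm = jj
                    if im < 0:
                        im = min(1, nx - 1)
                    if im > nx - 1:
                        im = max(nx - 2, 0)
                    if jm < 0:
                        jm = min(1, ny - 1)
                    if jm > ny - 1:
                        jm = max(ny - 2, 0)
                    w = Dn[k] / dx2
                    rows.append(n); cols.append(nid(im, jm, k)); vals.append(w)
                    rows.append(n); cols.append(n); vals.append(-w)
                # vertical neighbours: single-material face permeability
                if nz > 1:
                    for kk in (k - 1, k + 1):
                        km = kk
                        iface = min(k, kk)  # face between levels iface, iface+1
                        if km < 0:
                            km = 1
                            iface = 0
                        if km > nz - 1:
                            km = nz - 2
                            iface = nz - 2
                        w = face_perm[iface] / kn[k] / dx2
                        rows.append(n); cols.append(nid(i, j, km)); vals.append(w)
                        rows.append(n); cols.append(n); vals.append(-w)
    A = sp.coo_matrix((vals, (rows, cols)), shape=(grid.n_nodes, grid.n_nodes)).tocsr()
    return A


def dense_steady_solution(
    grid: SimulationGrid,
    tissue: TissueParams = TissueParams(),
    membrane: MembraneParams = MembraneParams(),
    window_po2: float = 0.0,
    tol: float = 1e-10,
    max_iter: int = 60,
) -> FieldState:
    """Steady state of the full nonlinear system by damped Newton iteration.

    Only for verification-sized grids (<= 20^3 nodes): the Jacobian is
    assembled densely enough that larger grids are refused. Residual
    (mmHg/s, max norm) is driven below ``tol``.
    """
    if grid.n_nodes > _MAX_NODES:
        raise ValueError(f"dense oracle limited to {_MAX_NODES} nodes, got {grid.n_nodes}")
    nx, ny, nz = grid.shape
    A = _assemble_diffusion(grid, tissue, membrane)
    react = (~grid.is_pdms)[None, None, :] * np.ones(grid.shape, bool)
    win3 = np.zeros(grid.shape, bool)
    win3[:, :, 0] = grid.window_mask
    react_f = (react & ~win3).ravel()
    win_f = win3.ravel()
    Mk, K, P0, P50 = tissue.consumption_rate, tissue.K, tissue.P0, tissue.P50

    P = np.full(grid.n_nodes, max(window_po2, 1.0))
    P[win_f] = window_po2

    def residual(Pv):
        F = A @ Pv
        Pr = Pv[react_f]
        F[react_f] += K * (1.0 - Pr / P0) - Mk * Pr / (Pr + P50)
        F[win_f] = Pv[win_f] - window_po2
        return F

    I = sp.identity(grid.n_nodes, format="csr")
    F = residual(P)
    norm = np.max(np.abs(F))
    for _ in range(max_iter):
        if norm < tol:
            break
        # Jacobian: diffusion + reaction diagonal; Dirichlet rows = identity
        dr = np.zeros(grid.n_nodes)
        Pr = P[react_f]
        dr[react_f] = -K / P0 - Mk * P50 / (Pr + P50) ** 2
        J = A + sp.diags(dr)
        J = J.tolil()
        for n in np.flatnonzero(win_f):
            J.rows[n] = [n]
            J.data[n] = [1.0]
        J = J.tocsr()
        dP = spsolve(J, -F)
        lam = 1.0
        while lam > 1e-6:
            Pn = P + lam * dP
            Fn = residual(np.maximum(Pn, 0.0))
            nn = np.max(np.abs(Fn))
            if nn < norm:
                P, F, norm = np.maximum(Pn, 0.0), Fn, nn
                break
            lam /= 2.0
        else:
            raise RuntimeError(f"Newton iteration stalled at residual {norm:.3g} mmHg/s")
    else:
        raise RuntimeError(f"Newton did not converge: residual {norm:.3g} mmHg/s")
    return FieldState(P.reshape(grid.shape), float("inf"))
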