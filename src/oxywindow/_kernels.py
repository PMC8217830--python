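"""Compiled inner loop of the explicit update.

Materials vary only along z, so the stencil needs just four 1D coefficient
arrays; the kernel fuses the Laplacian, the reaction terms and the
semi-implicit division into a single pass over the grid. Semantics are
identical to ``solver._step_numpy`` (tested for bitwise-level agreement).
"""

import numba
import numpy as np

NUMBA_AVAILABLE = True


@numba.njit(cache=True, fastmath=False)
def step_kernel(P, Pn, Dz, kz, wz, react, dt, inv_dx2, K, P0, Mk, P50):
    nx, ny, nz = P.shape
    implicit = 1.0 / (1.0 + dt * K / P0)
    for i in range(nx):
        im = i - 1
        if i == 0:
            im = min(1, nx - 1)
        ip = i + 1
        if i == nx - 1:
            ip = max(nx - 2, 0)
        for j in range(ny):
            jm = j - 1
            if j == 0:
                jm = min(1, ny - 1)
            jp = j + 1
            if j == ny - 1:
                jp = max(ny - 2, 0)
            for k in range(nz):
                c = P[i, j, k]
                lat = Dz[k] * (
                    P[im, j, k] + P[ip, j, k] + P[i, jm, k] + P[i, jp, k] - 4.0 * c
                )
                vert = 0.0
                if nz > 1:
                    if k < nz - 1:
                        vert += wz[k] * (P[i, j, k + 1] - c)
                    else:
                        vert += wz[nz - 2] * (P[i, j, nz - 2] - c)
                    if k > 0:
                        vert += wz[k - 1] * (P[i, j, k - 1] - c)
                    else:
                        vert += wz[0] * (P[i, j, 1] - c)
                    vert /= kz[k]
                lap = (lat + vert) * inv_dx2
                if react[k]:
                    Pn[i, j, k] = (
                        c + dt * (lap + K - Mk * c / (c + P50))
                    ) * implicit
                else:
                    Pn[i, j, k] = c + dt * lap
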