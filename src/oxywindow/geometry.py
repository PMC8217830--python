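"""Simulation domain: PDMS slab under a tissue block, with gas-exchange windows.

Coordinate convention (fixed project-wide): z = 0 is the glass plane where the
exchange windows sit; z increases into the tissue; the tissue surface is at
z = h_pdms. "Depth from the glass" is z, "depth from the tissue surface" is
z - h_pdms.

The grid is vertex-centred with isotropic spacing dx: an axis of physical
length L carries floor(L/dx) + 1 nodes. A window boundary node is any z = 0
node whose (x, y) lies inside the closed window rectangle, which makes mask
sizes exact fencepost counts and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_EPS = 1e-9


class GeometryError(ValueError):
    """Raised for invalid domain or window-layout geometry."""


@dataclass(frozen=True)
class DomainSpec:
    """Physical extents and grid spacing of the simulation box (um).

    ``h_pdms`` and ``Lz_tissue`` must be integer multiples of ``dx`` so the
    material interface falls on a grid plane. ``h_pdms = 0`` is allowed and
    gives a pure-tissue block (used by the 1D verification columns).
    """

    Lx: float = 1200.0
    Ly: float = 1000.0
    Lz_tissue: float = 300.0
    h_pdms: float = 25.0
    dx: float = 5.0

    def __post_init__(self) -> None:
        for name in ("Lx", "Ly", "Lz_tissue", "dx"):
            if not getattr(self, name) > 0:
                raise GeometryError(f"DomainSpec.{name} must be > 0")
        if self.h_pdms < 0:
            raise GeometryError("DomainSpec.h_pdms must be >= 0")
        for name in ("h_pdms", "Lz_tissue"):
            ratio = getattr(self, name) / self.dx
            if abs(ratio - round(ratio)) > _EPS:
                raise GeometryError(
                    f"DomainSpec.{name}={getattr(self, name)} is not an integer "
                    f"multiple of dx={self.dx}; the material interface must be grid-aligned"
                )

    @property
    def Lz(self) -> float:
        """Total domain height: membrane plus tissue."""
        return self.h_pdms + self.Lz_tissue


@dataclass(frozen=True)
class WindowLayout:
    """Rectangular gas-exchange window footprints on the z = 0 glass plane.

    Each rectangle is (center_x, center_y, length_x, length_y) in um, in
    absolute domain coordinates. Rectangles must be pairwise disjoint.
    """

    rectangles: tuple[tuple[float, float, float, float], ...] = ()

    def __post_init__(self) -> None:
        rects = tuple(tuple(float(v) for v in r) for r in self.rectangles)
        object.__setattr__(self, "rectangles", rects)
        for cx, cy, lx, ly in rects:
            if lx <= 0 or ly <= 0:
                raise GeometryError("window dimensions must be > 0")
        for i in range(len(rects)):
            for j in range(i + 1, len(rects)):
                if _overlap(rects[i], rects[j]):
                    raise GeometryError(f"windows {i} and {j} overlap")

    def __len__(self) -> int:
        return len(self.rectangles)


def _overlap(a, b) -> bool:
    ax, ay, alx, aly = a
    bx, by, blx, bly = b
    return (abs(ax - bx) < (alx + blx) / 2 - _EPS) and (abs(ay - by) < (aly + bly) / 2 - _EPS)


def single_window_layout(
    spec: DomainSpec, window_length: float = 400.0, window_width: float = 200.0
) -> WindowLayout:
    """One window centred on the domain footprint, long axis along x."""
    return WindowLayout(((spec.Lx / 2, spec.Ly / 2, window_length, window_width),))


def five_window_layout(
    spec: DomainSpec,
    pitch: float,
    window_length: float = 400.0,
    window_width: float = 200.0,
    count: int = 5,
) -> WindowLayout:
    """``count`` collinear windows along x, equally spaced by ``pitch`` (um),
    centred on the domain footprint. The fabricated slides carry five windows
    so the muscle can be positioned over whichever one sits best; the pitch is
    a design choice, so it is a required argument.
    """
    if count < 1:
        raise GeometryError("count must be >= 1")
    if count > 1 and pitch <= window_length:
        raise GeometryError(
            f"pitch {pitch} um must exceed the window length {window_length} um along the layout axis"
        )
    offset0 = -(count - 1) / 2 * pitch
    rects = tuple(
        (spec.Lx / 2 + offset0 + i * pitch, spec.Ly / 2, window_length, window_width)
        for i in range(count)
    )
    return WindowLayout(rects)


@dataclass(frozen=True)
class SimulationGrid:
    """Discretised domain: coordinates, region labels and boundary masks.

    ``is_pdms`` labels each z-level: True for 0 <= z <= h_pdms (the interface
    plane belongs to the membrane), False above. ``window_mask`` marks the
    z = 0 nodes held at the chamber PO2; every other boundary node is
    zero-flux (the glass, the tissue sides and the tissue top).
    """

    spec: DomainSpec
    layout: WindowLayout
    nx: int = field(init=False)
    ny: int = field(init=False)
    nz: int = field(init=False)
    x: np.ndarray = field(init=False, repr=False, compare=False)
    y: np.ndarray = field(init=False, repr=False, compare=False)
    z: np.ndarray = field(init=False, repr=False, compare=False)
    iz_interface: int = field(init=False)
    is_pdms: np.ndarray = field(init=False, repr=False, compare=False)
    window_mask: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        spec, layout = self.spec, self.layout
        dx = spec.dx
        nx = int(np.floor(spec.Lx / dx + _EPS)) + 1
        ny = int(np.floor(spec.Ly / dx + _EPS)) + 1
        nz = int(np.floor(spec.Lz / dx + _EPS)) + 1
        x = np.arange(nx) * dx
        y = np.arange(ny) * dx
        z = np.arange(nz) * dx
        iz_interface = int(round(spec.h_pdms / dx))
        if spec.h_pdms > 0:
            is_pdms = z <= spec.h_pdms + _EPS
        else:  # zero-thickness membrane: the whole column is tissue
            is_pdms = np.zeros(nz, dtype=bool)
        mask = np.zeros((nx, ny), dtype=bool)
        for cx, cy, lx, ly in layout.rectangles:
            x0, x1 = cx - lx / 2, cx + lx / 2
            y0, y1 = cy - ly / 2, cy + ly / 2
            if x0 < -_EPS or y0 < -_EPS or x1 > spec.Lx + _EPS or y1 > spec.Ly + _EPS:
                raise GeometryError(
                    f"window ({cx}, {cy}, {lx}, {ly}) extends outside the "
                    f"{spec.Lx} x {spec.Ly} um footprint"
                )
            inx = (x >= x0 - _EPS) & (x <= x1 + _EPS)
            iny = (y >= y0 - _EPS) & (y <= y1 + _EPS)
            mask |= inx[:, None] & iny[None, :]
        for name, val in (
            ("nx", nx), ("ny", ny), ("nz", nz), ("iz_interface", iz_interface),
        ):
            object.__setattr__(self, name, val)
        for name, val in (
            ("x", x), ("y", y), ("z", z), ("is_pdms", is_pdms), ("window_mask", mask),
        ):
            val.setflags(write=False)
            object.__setattr__(self, name, val)

    # identity is fully determined by spec + layout
    def __hash__(self) -> int:
        return hash((self.spec, self.layout))

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny * self.nz

    def nearest_index(self, point: tuple[float, float, float]) -> tuple[int, int, int]:
        """Grid index of the node nearest a physical (x, y, z) point in um."""
        px, py, pz = point
        if not (0 <= px <= self.spec.Lx and 0 <= py <= self.spec.Ly and 0 <= pz <= self.spec.Lz):
            raise GeometryError(f"point {point} lies outside the domain")
        dx = self.spec.dx
        return (
            min(int(round(px / dx)), self.nx - 1),
            min(int(round(py / dx)), self.ny - 1),
            min(int(round(pz / dx)), self.nz - 1),
        )

    def summary(self) -> dict:
        """Grid audit numbers: node counts, mask sizes, interface level."""
        return {
            "shape": self.shape,
            "n_nodes": self.n_nodes,
            "dx_um": self.spec.dx,
            "iz_interface": self.iz_interface,
            "n_pdms_planes": int(self.is_pdms.sum()),
            "n_window_nodes": int(self.window_mask.sum()),
            "n_glass_zero_flux_nodes": int((~self.window_mask).sum()),
        }


def build_grid(spec: DomainSpec, layout: WindowLayout) -> SimulationGrid:
    """Assemble the simulation grid; validates that every window rectangle
    lies inside the domain footprint."""
    return SimulationGrid(spec, layout)
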