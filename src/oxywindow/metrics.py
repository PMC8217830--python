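"""Perturbation-extent metrics: how local is a local oxygen challenge?

The reach of a window challenge is defined by a gradient threshold: a point
still "feels" the perturbation while the magnitude of the directional
derivative of PO2 exceeds e^-4 (~0.0183) mmHg/um. Penetration depth is
evaluated along the vertical line through the window centroid; lateral
extents march outward from the window-edge midpoints along the window's
long (x) and short (y) axes, in every horizontal tissue plane; the affected
area at a plane is the window footprint grown by twice the lateral extents
there. Derivatives are second-order central differences on the grid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field

import numpy as np

from .geometry import SimulationGrid, GeometryError
from .solver import FieldState

#: default gradient threshold, mmHg/um
DEFAULT_THRESHOLD = math.exp(-4.0)


@dataclass(frozen=True)
class ExtentCriterion:
    """Gradient-magnitude threshold terminating the perturbation's reach."""

    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")


@dataclass
class ExtentReport:
    """Summary of a challenge's spatial reach, all lengths in um."""

    depth_from_tissue_surface: float
    lateral_long_axis: float
    lateral_short_axis: float
    affected_area: tuple[float, float]
    area_plane_z: float
    threshold: float
    metadata: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


def _window_rect(grid: SimulationGrid):
    if len(grid.layout) != 1:
        raise GeometryError("extent metrics require a single-window layout")
    return grid.layout.rectangles[0]


def _dP(field: FieldState, grid: SimulationGrid, axis: int) -> np.ndarray:
    """Central-difference derivative of PO2 along one grid axis, mmHg/um."""
    return np.gradient(field.P, grid.spec.dx, axis=axis)


def penetration_depth(
    field: FieldState, grid: SimulationGrid, criterion: ExtentCriterion = ExtentCriterion()
) -> float:
    """Depth below the tissue surface still perturbed by the window, um.

    Walks the vertical line through the window centroid and returns the
    largest z at which |dP/dz| >= threshold, minus the membrane thickness;
    0 if the gradient never reaches threshold above the tissue surface.
    """
    cx, cy, _, _ = _window_rect(grid)
    ix, iy, _ = grid.nearest_index((cx, cy, 0.0))
    g = np.abs(_dP(field, grid, axis=2)[ix, iy, :])
    h = grid.spec.h_pdms
    above = np.flatnonzero((g >= criterion.threshold) & (grid.z > h + 1e-9))
    if above.size == 0:
        return 0.0
    return float(grid.z[above[-1]] - h)


def _edge_profile(
    field: FieldState, grid: SimulationGrid, axis: str, criterion: ExtentCriterion
) -> tuple[np.ndarray, np.ndarray]:
    """Per-tissue-plane lateral extent along one window axis.

    Returns (z of tissue planes, extent per plane). For each horizontal
    plane at or above the tissue surface, marches outward from the
    window-edge midpoint along the chosen axis and measures the distance to
    the first node whose |directional derivative| drops below threshold.
    """
    cx, cy, lx, ly = _window_rect(grid)
    long_is_x = lx >= ly
    # "long"/"short" refer to the window's own axes
    march_x = (axis == "long") == long_is_x
    if march_x:
        start = (cx + lx / 2, cy, 0.0)
        deriv = _dP(field, grid, axis=0)
    else:
        start = (cx, cy + ly / 2, 0.0)
        deriv = _dP(field, grid, axis=1)
    i0, j0, _ = grid.nearest_index(start)
    tissue_planes = np.flatnonzero(~grid.is_pdms)
    if tissue_planes.size == 0:
        tissue_planes = np.arange(grid.nz)
    dx = grid.spec.dx
    extents = np.empty(tissue_planes.size)
    for n, iz in enumerate(tissue_planes):
        if march_x:
            ray = np.abs(deriv[i0:, j0, iz])
        else:
            ray = np.abs(deriv[i0, j0:, iz])
        below = np.flatnonzero(ray < criterion.threshold)
        extents[n] = (below[0] if below.size else ray.size - 1) * dx
    return grid.z[tissue_planes], extents


def lateral_extent(
    field: FieldState,
    grid: SimulationGrid,
    axis: str = "long",
    criterion: ExtentCriterion = ExtentCriterion(),
    plane_z: float | None = None,
) -> float:
    """Lateral reach beyond the window edge along its long or short axis, um.

    With ``plane_z`` (um from the glass) the extent in that single
    horizontal plane is returned; otherwise the maximum over all tissue
    planes.
    """
    if axis not in ("long", "short"):
        raise ValueError("axis must be 'long' or 'short'")
    zs, extents = _edge_profile(field, grid, axis, criterion)
    if plane_z is None:
        return float(extents.max())
    i = int(np.argmin(np.abs(zs - plane_z)))
    if abs(zs[i] - plane_z) > grid.spec.dx / 2 + 1e-9:
        raise GeometryError(f"plane z={plane_z} um is not a tissue plane")
    return float(extents[i])


def affected_area(
    field: FieldState,
    grid: SimulationGrid,
    plane_z: float,
    criterion: ExtentCriterion = ExtentCriterion(),
) -> tuple[float, float]:
    """Affected-region dimensions at a horizontal plane, um x um.

    (window length + 2 * long-axis extent, window width + 2 * short-axis
    extent) evaluated at ``plane_z`` um above the glass. The plane must lie
    in the tissue, not the membrane.
    """
    if plane_z < grid.spec.h_pdms - 1e-9:
        raise GeometryError(
            f"plane z={plane_z} um lies inside the membrane (h_pdms={grid.spec.h_pdms} um)"
        )
    _, _, lx, ly = _window_rect(grid)
    e_long = lateral_extent(field, grid, "long", criterion, plane_z=plane_z)
    e_short = lateral_extent(field, grid, "short", criterion, plane_z=plane_z)
    length, width = (lx, ly) if lx >= ly else (ly, lx)
    return (length + 2 * e_long, width + 2 * e_short)


def settle_time(times, values, tol: float = 0.1) -> float:
    """First time after which a probe trace stays within ``tol`` mmHg of its
    final value, in seconds from the start of the trace.

    Returns ``inf`` when the trace is still moving at its end (the final
    two samples differ by at least ``tol``), i.e. it never settled.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.ndim != 1 or values.shape[0] != times.shape[0]:
        raise ValueError("times and values must align on the first axis")
    within = np.abs(values - values[-1]) < tol
    # first index of the trailing all-within run
    off = np.flatnonzero(~within)
    first = 0 if off.size == 0 else off[-1] + 1
    if first >= len(times) - 1 and len(times) > 1:
        if np.abs(values[-2] - values[-1]) >= tol:
            return float("inf")
    return float(times[first] - times[0])


def extract_section(
    field: FieldState, grid: SimulationGrid, kind: str, coordinate: float
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray], dict]:
    """Cut a 2D section out of the field for plotting or export.

    kind: 'z-plane' (horizontal, like the imaging plane), 'x-slice' or
    'y-slice' (vertical). ``coordinate`` in um is snapped to the nearest
    grid plane (recorded in the metadata). Returns (array, (axis1, axis2),
    metadata); axes carry physical um coordinates.
    """
    dx = grid.spec.dx
    if kind == "z-plane":
        iz = int(round(coordinate / dx))
        if not 0 <= iz < grid.nz:
            raise GeometryError(f"z={coordinate} um outside domain")
        arr, axes = field.P[:, :, iz], (grid.x, grid.y)
        meta = {"kind": kind, "requested_um": coordinate, "used_um": float(grid.z[iz]),
                "axes": ("x", "y"), "index": iz}
    elif kind == "x-slice":
        ix = int(round(coordinate / dx))
        if not 0 <= ix < grid.nx:
            raise GeometryError(f"x={coordinate} um outside domain")
        arr, axes = field.P[ix, :, :], (grid.y, grid.z)
        meta = {"kind": kind, "requested_um": coordinate, "used_um": float(grid.x[ix]),
                "axes": ("y", "z"), "index": ix}
    elif kind == "y-slice":
        iy = int(round(coordinate / dx))
        if not 0 <= iy < grid.ny:
            raise GeometryError(f"y={coordinate} um outside domain")
        arr, axes = field.P[:, iy, :], (grid.x, grid.z)
        meta = {"kind": kind, "requested_um": coordinate, "used_um": float(grid.y[iy]),
                "axes": ("x", "z"), "index": iy}
    else:
        raise ValueError("kind must be 'z-plane', 'x-slice' or 'y-slice'")
    return arr.copy(), axes, meta


def extent_report(
    field: FieldState,
    grid: SimulationGrid,
    criterion: ExtentCriterion = ExtentCriterion(),
    area_plane_z: float = 75.0,
) -> ExtentReport:
    """One-shot summary: depth, lateral extents and affected area.

    ``area_plane_z`` is measured from the glass surface (default 75 um,
    the typical imaging plane 50 um into the tissue).
    """
    cx, cy, lx, ly = _window_rect(grid)
    return ExtentReport(
        depth_from_tissue_surface=penetration_depth(field, grid, criterion),
        lateral_long_axis=lateral_extent(field, grid, "long", criterion),
        lateral_short_axis=lateral_extent(field, grid, "short", criterion),
        affected_area=affected_area(field, grid, area_plane_z, criterion),
        area_plane_z=area_plane_z,
        threshold=criterion.threshold,
        metadata={
            "window_center_um": (cx, cy),
            "window_size_um": (lx, ly),
            "derivative": "second-order central difference, magnitude",
            "depth_locus": "vertical line through window centroid",
            "lateral_locus": "axis-aligned rays from window-edge midpoints, max over tissue planes",
            "grid_dx_um": grid.spec.dx,
            "field_time_s": field.t,
        },
    )
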