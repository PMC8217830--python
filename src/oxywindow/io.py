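"""Deterministic output writers: CSV traces/sections, HDF5 and legacy-ASCII
VTK field snapshots, JSON extent reports.

Axis conventions in all files: x fastest, origin at the domain corner,
z = 0 is the glass plane. Units are stated in headers/attributes so files
are interpretable without this package.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import h5py
import numpy as np

from .geometry import SimulationGrid
from .metrics import ExtentReport
from .solver import FieldState, ProtocolResult


def write_probe_csv(path, result: ProtocolResult) -> None:
    """Probe traces: one row per output time, PO2 columns in mmHg."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        header = ["t_s"] + [
            f"po2_mmHg_x{p[0]:g}_y{p[1]:g}_z{p[2]:g}" for p in result.probe_points
        ]
        w.writerow(header)
        for t, row in zip(result.times, result.probe_po2):
            w.writerow([f"{t:.6g}"] + [f"{v:.6g}" for v in row])


def write_section_csv(path, arr: np.ndarray, axes, meta: dict) -> None:
    """2D section as a CSV matrix; first row/column carry um coordinates."""
    path = Path(path)
    a1, a2 = axes
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([f"# section {meta['kind']} at {meta['used_um']:g} um; "
                    f"axes {meta['axes'][0]}/{meta['axes'][1]} in um; values PO2 in mmHg"])
        w.writerow([""] + [f"{v:g}" for v in a2])
        for i, v1 in enumerate(a1):
            w.writerow([f"{v1:g}"] + [f"{x:.6g}" for x in arr[i]])


def write_field_hdf5(path, field: FieldState, grid: SimulationGrid) -> None:
    """Full field with axis coordinates and unit attributes."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("po2", data=field.P)
        d.attrs["units"] = "mmHg"
        d.attrs["axis_order"] = "x,y,z"
        f.create_dataset("x_um", data=grid.x)
        f.create_dataset("y_um", data=grid.y)
        f.create_dataset("z_um", data=grid.z)
        f.attrs["t_s"] = field.t
        f.attrs["h_pdms_um"] = grid.spec.h_pdms
        f.attrs["dx_um"] = grid.spec.dx


def write_field_vtk(path, field: FieldState, grid: SimulationGrid) -> None:
    """Legacy-ASCII VTK STRUCTURED_POINTS snapshot (openable in ParaView).

    VTK expects x to vary fastest, so the (x, y, z)-indexed array is
    flattened in Fortran order.
    """
    dx = grid.spec.dx
    P = field.P
    nx, ny, nz = P.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"PO2 field (mmHg) at t={field.t:g} s; z=0 is the glass plane\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {dx:g} {dx:g} {dx:g}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write("SCALARS po2_mmHg float 1\nLOOKUP_TABLE default\n")
        flat = P.ravel(order="F")
        for i in range(0, flat.size, 9):
            fh.write(" ".join(f"{v:.6g}" for v in flat[i:i + 9]) + "\n")


def write_extent_json(path, report: ExtentReport) -> None:
    Path(path).write_text(report.to_json(indent=2) + "\n")


def read_field_hdf5(path) -> tuple[np.ndarray, dict]:
    """Load a snapshot back; returns (po2 array, metadata)."""
    with h5py.File(path, "r") as f:
        P = f["po2"][...]
        meta = {
            "t_s": float(f.attrs["t_s"]),
            "h_pdms_um": float(f.attrs["h_pdms_um"]),
            "dx_um": float(f.attrs["dx_um"]),
            "x_um": f["x_um"][...],
            "y_um": f["y_um"][...],
            "z_um": f["z_um"][...],
        }
    return P, meta


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")
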