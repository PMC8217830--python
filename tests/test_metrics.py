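"""Extent metrics against closed-form synthetic fields and invariants."""

import math

import numpy as np
import pytest

import oxywindow as ow
from oxywindow.geometry import GeometryError
from oxywindow.metrics import DEFAULT_THRESHOLD


def _grid(Lx=400.0, Ly=200.0, Lz=160.0, h=20.0, dx=10.0, win=(80.0, 40.0)):
    spec = ow.DomainSpec(Lx=Lx, Ly=Ly, Lz_tissue=Lz, h_pdms=h, dx=dx)
    return ow.build_grid(spec, ow.single_window_layout(spec, *win))


def _exp_depth_field(grid, A, lam):
    """Laterally uniform P = A exp(-(z - h)/lam): gradient-threshold depth
    has the closed form lam * ln(A / (lam * theta))."""
    z = grid.z[None, None, :]
    P = A * np.exp(-(z - grid.spec.h_pdms) / lam) * np.ones(grid.shape)
    return ow.FieldState(P, 0.0)


def _exp_lateral_field(grid, B, ell):
    """P decaying exponentially with distance outside the window footprint
    along x and y separately (rays are axis-aligned, so each march sees a
    pure 1D exponential)."""
    cx, cy, lx, ly = grid.layout.rectangles[0]
    sx = np.maximum(np.abs(grid.x - cx) - lx / 2, 0.0)
    sy = np.maximum(np.abs(grid.y - cy) - ly / 2, 0.0)
    s = np.maximum(sx[:, None], sy[None, :])
    P = B * np.exp(-s / ell)
    return ow.FieldState(np.repeat(P[:, :, None], grid.nz, axis=2), 0.0)


class TestPenetrationDepth:
    def test_exponential_closed_form(self):
        grid = _grid(Lz=160.0)
        A, lam = 20.0, 30.0
        field = _exp_depth_field(grid, A, lam)
        expected = lam * math.log(A / (lam * DEFAULT_THRESHOLD))
        got = ow.penetration_depth(field, grid)
        assert got == pytest.approx(expected, abs=grid.spec.dx)

    def test_uniform_field_zero(self):
        grid = _grid()
        field = ow.FieldState(np.full(grid.shape, 40.0))
        assert ow.penetration_depth(field, grid) == 0.0


class TestLateralExtent:
    @pytest.mark.parametrize("axis", ["long", "short"])
    def test_exponential_closed_form(self, axis):
        grid = _grid()
        B, ell = 10.0, 25.0
        field = _exp_lateral_field(grid, B, ell)
        expected = ell * math.log(B / (ell * DEFAULT_THRESHOLD))
        got = ow.lateral_extent(field, grid, axis)
        assert got == pytest.approx(expected, abs=grid.spec.dx)

    def test_uniform_field_zero(self):
        grid = _grid()
        field = ow.FieldState(np.full(grid.shape, 40.0))
        assert ow.lateral_extent(field, grid, "long") == 0.0
        assert ow.lateral_extent(field, grid, "short") == 0.0

    def test_translation_invariance(self):
        """Shifting the window (and its field) one cell leaves extents put."""
        spec = ow.DomainSpec(Lx=400, Ly=200, Lz_tissue=100, h_pdms=20, dx=10)
        vals = {}
        for shift in (0.0, 10.0):
            layout = ow.WindowLayout(((spec.Lx / 2 + shift, spec.Ly / 2, 80.0, 40.0),))
            grid = ow.build_grid(spec, layout)
            field = _exp_lateral_field(grid, 10.0, 25.0)
            vals[shift] = (
                ow.lateral_extent(field, grid, "long"),
                ow.lateral_extent(field, grid, "short"),
            )
        assert vals[0.0][0] == pytest.approx(vals[10.0][0], abs=spec.dx)
        assert vals[0.0][1] == pytest.approx(vals[10.0][1], abs=spec.dx)

    def test_threshold_monotonicity(self):
        grid = _grid()
        field = _exp_lateral_field(grid, 10.0, 25.0)
        thetas = [0.005, 0.01, DEFAULT_THRESHOLD, 0.05, 0.1]
        ext = [
            ow.lateral_extent(field, grid, "long", ow.ExtentCriterion(t)) for t in thetas
        ]
        dep = [
            ow.penetration_depth(_exp_depth_field(grid, 20.0, 30.0), grid,
                                 ow.ExtentCriterion(t))
            for t in thetas
        ]
        assert all(a >= b for a, b in zip(ext, ext[1:]))
        assert all(a >= b for a, b in zip(dep, dep[1:]))


class TestAffectedArea:
    def test_constructive_identity(self):
        grid = _grid()
        field = _exp_lateral_field(grid, 10.0, 25.0)
        plane = 60.0
        a_long = ow.lateral_extent(field, grid, "long", plane_z=plane)
        a_short = ow.lateral_extent(field, grid, "short", plane_z=plane)
        area = ow.affected_area(field, grid, plane)
        assert area == (80.0 + 2 * a_long, 40.0 + 2 * a_short)

    def test_uniform_field_window_footprint(self):
        grid = _grid()
        field = ow.FieldState(np.full(grid.shape, 40.0))
        assert ow.affected_area(field, grid, 60.0) == (80.0, 40.0)

    def test_plane_in_membrane_rejected(self):
        grid = _grid()
        field = ow.FieldState(np.full(grid.shape, 40.0))
        with pytest.raises(GeometryError):
            ow.affected_area(field, grid, 10.0)


class TestSettleTime:
    def test_constant_trace(self):
        t = np.linspace(0, 5, 100)
        assert ow.settle_time(t, np.full_like(t, 30.0)) == 0.0

    def test_exponential_closed_form(self):
        tau, delta, tol = 0.8, 6.0, 0.1
        t = np.linspace(0, 12, 4001)
        trace = 30.0 - delta * np.exp(-t / tau)
        expected = tau * math.log(delta / tol)
        assert ow.settle_time(t, trace, tol) == pytest.approx(expected, abs=0.01)

    def test_never_settles(self):
        t = np.linspace(0, 5, 50)
        assert ow.settle_time(t, 10.0 * t) == float("inf")


class TestExtractSection:
    def test_zplane_shape_and_roundtrip(self):
        grid = _grid()
        rng = np.random.default_rng(7)
        field = ow.FieldState(rng.random(grid.shape))
        arr, (a1, a2), meta = ow.extract_section(field, grid, "z-plane", 60.0)
        assert arr.shape == (grid.nx, grid.ny)
        assert meta["used_um"] == 60.0 and meta["axes"] == ("x", "y")
        assert np.array_equal(arr, field.P[:, :, meta["index"]])

    def test_vertical_slice_orientation(self):
        grid = _grid()
        field = ow.FieldState(np.zeros(grid.shape))
        arr, (a1, a2), meta = ow.extract_section(field, grid, "y-slice", grid.spec.Ly / 2)
        assert arr.shape == (grid.nx, grid.nz)
        assert meta["axes"] == ("x", "z")

    def test_outside_domain_rejected(self):
        grid = _grid()
        field = ow.FieldState(np.zeros(grid.shape))
        with pytest.raises(GeometryError):
            ow.extract_section(field, grid, "z-plane", 1e4)
        with pytest.raises(ValueError):
            ow.extract_section(field, grid, "diagonal", 0.0)


def test_extent_report_schema():
    grid = _grid()
    field = _exp_lateral_field(grid, 10.0, 25.0)
    rep = ow.extent_report(field, grid, area_plane_z=60.0)
    payload = rep.to_json()
    for key in ("depth_from_tissue_surface", "lateral_long_axis",
                "lateral_short_axis", "affected_area", "threshold"):
        assert key in payload
    assert rep.metadata["grid_dx_um"] == grid.spec.dx
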