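"""Laplace solver verification: symmetry, maximum principle, manufactured
solutions, the conformal-map oracle and mesh convergence."""

import numpy as np
import pytest

from slantdep import ChannelGeometry, MeshSpec
from slantdep.field_solver import (
    FieldSolution,
    convergence_study,
    electric_field,
    grad_e2_x,
    solve_fields,
    solve_potential,
    top_line_fom,
)

from conftest import conformal_oracle


@pytest.fixture(scope="module")
def standard_geometry() -> ChannelGeometry:
    return ChannelGeometry.from_microns(25, 40, 10)


@pytest.fixture(scope="module")
def standard_solution(standard_geometry) -> FieldSolution:
    return solve_fields(standard_geometry, 2.0)


class TestGeometry:
    def test_domain_width_identity(self, standard_geometry):
        g = standard_geometry
        assert g.domain_width == pytest.approx(
            g.electrode_gap + 2 * g.electrode_width + 2 * g.padding)

    def test_default_padding_rule(self):
        shallow = ChannelGeometry.from_microns(25, 100, 10)
        deep = ChannelGeometry.from_microns(75, 40, 10)
        assert shallow.padding == pytest.approx(100e-6)  # max(2h, w) = w
        assert deep.padding == pytest.approx(150e-6)     # max(2h, w) = 2h

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ChannelGeometry.from_microns(0, 40, 10)
        with pytest.raises(ValueError):
            ChannelGeometry.from_microns(25, 40, 10, electrode_angle=90.0)


class TestSolvePotential:
    def test_zero_drive_gives_zero_field(self, standard_geometry):
        sol = solve_fields(standard_geometry, 0.0)
        assert np.all(sol.potential == 0.0)
        assert np.all(sol.e_x == 0.0)
        assert top_line_fom(sol).value == 0.0

    def test_electrode_nodes_pinned_to_dirichlet_values(self, standard_solution):
        sol = standard_solution
        x1, x2, x3, x4 = sol.geometry.electrode_edges
        on_left = (sol.x >= x1) & (sol.x <= x2)
        on_right = (sol.x >= x3) & (sol.x <= x4)
        assert np.all(sol.potential[0, on_left] == sol.amplitude)
        assert np.all(sol.potential[0, on_right] == -sol.amplitude)

    def test_antisymmetry_about_gap_centerline(self, standard_solution):
        v = standard_solution.potential
        # grid is symmetric for equal electrode widths: mirror is column flip
        assert np.abs(v + v[:, ::-1]).max() < 1e-12

    def test_maximum_principle(self, standard_solution):
        v = standard_solution.potential
        amp = standard_solution.amplitude
        assert v.min() >= -amp - 1e-12
        assert v.max() <= amp + 1e-12

    def test_solution_linear_in_drive(self, standard_geometry, standard_solution):
        for factor in (2.0, 0.5):
            scaled = solve_potential(standard_geometry, 2.0 * factor)
            assert np.allclose(scaled.potential,
                               factor * standard_solution.potential,
                               rtol=1e-12, atol=1e-14)

    def test_gap_resolved_by_at_least_eight_nodes(self, standard_solution):
        x1, x2, x3, x4 = standard_solution.geometry.electrode_edges
        in_gap = (standard_solution.x >= x2) & (standard_solution.x <= x3)
        assert in_gap.sum() >= 8

    def test_conformal_map_oracle_agreement(self):
        # wide electrodes, shallow gap: w >> h >> g
        geo = ChannelGeometry(height=40e-6, electrode_width=400e-6,
                              electrode_gap=4e-6)
        sol = solve_potential(geo, 2.0, MeshSpec(refinement_level=2))
        x1, x2, x3, x4 = geo.electrode_edges
        xc, a = 0.5 * (x2 + x3), geo.electrode_gap / 2.0
        xx, yy = np.meshgrid(sol.x - xc, sol.y)
        expected = conformal_oracle(xx, yy, a, geo.height)
        r = np.hypot(xx, yy)
        r_edge = np.hypot(np.minimum(np.abs(xx + a), np.abs(xx - a)), yy)
        # compare near the gap, outside a small ring around the two corner
        # singularities where pointwise FD values converge only as sqrt(h)
        mask = (r < geo.height / 2.0) & (r_edge > geo.electrode_gap / 4.0)
        err = np.abs(sol.potential - expected)[mask].max()
        assert err < 0.03

    def test_padding_insensitivity(self, standard_geometry, fom_um):
        base = fom_um(25, 40, 10)
        doubled = ChannelGeometry.from_microns(
            25, 40, 10, lateral_padding=2 * standard_geometry.padding)
        fom2 = top_line_fom(solve_fields(doubled, 2.0)).value
        assert abs(fom2 - base) / base < 0.01


class TestElectricField:
    def test_uniform_potential_gives_zero_field(self, standard_solution):
        sol = FieldSolution(
            x=standard_solution.x, y=standard_solution.y,
            potential=np.ones_like(standard_solution.potential),
            geometry=standard_solution.geometry, amplitude=1.0,
            mesh_spacing=standard_solution.mesh_spacing, refinement_level=0)
        electric_field(sol)
        assert np.abs(sol.e_x).max() < 1e-8
        assert np.abs(sol.e_y).max() < 1e-8

    def test_manufactured_bilinear_potential(self, standard_solution):
        # V = x*y is harmonic; second-order differences recover E = (-y, -x)
        # exactly, boundaries included
        x, y = standard_solution.x, standard_solution.y
        xx, yy = np.meshgrid(x, y)
        sol = FieldSolution(
            x=x, y=y, potential=xx * yy,
            geometry=standard_solution.geometry, amplitude=1.0,
            mesh_spacing=standard_solution.mesh_spacing, refinement_level=0)
        electric_field(sol)
        assert np.allclose(sol.e_x, -yy, rtol=1e-9, atol=1e-12)
        assert np.allclose(sol.e_y, -xx, rtol=1e-9, atol=1e-12)

    def test_second_order_convergence_on_harmonic_field(self):
        # V = sin(kx) sinh(ky): field error drops ~4x when spacing halves
        k = 2 * np.pi / 50e-6
        geo = ChannelGeometry.from_microns(25, 40, 10)
        errs = []
        for n in (41, 81):
            x = np.linspace(0.0, 50e-6, n)
            y = np.linspace(0.0, 25e-6, n)
            xx, yy = np.meshgrid(x, y)
            sol = FieldSolution(x=x, y=y,
                                potential=np.sin(k * xx) * np.sinh(k * yy),
                                geometry=geo, amplitude=1.0,
                                mesh_spacing=x[1], refinement_level=0)
            electric_field(sol)
            ex_true = -k * np.cos(k * xx) * np.sinh(k * yy)
            errs.append(np.abs(sol.e_x - ex_true).max())
        assert errs[0] / errs[1] > 3.0


class TestGradE2X:
    def test_quadratic_drive_scaling(self, standard_geometry, standard_solution):
        sol10 = solve_fields(standard_geometry, 10.0)
        scale = np.abs(standard_solution.grad_e2_x).max()
        assert np.allclose(sol10.grad_e2_x, 25.0 * standard_solution.grad_e2_x,
                           rtol=1e-8, atol=25.0 * scale * 1e-10)

    def test_antisymmetric_about_gap_centerline(self, standard_solution):
        g = standard_solution.grad_e2_x
        scale = np.abs(g).max()
        assert np.abs(g + g[:, ::-1]).max() / scale < 1e-9

    def test_requires_field(self, standard_geometry):
        sol = solve_potential(standard_geometry, 2.0)
        with pytest.raises(ValueError):
            grad_e2_x(sol)


class TestTopLineFom:
    def test_global_gradient_maximum_sits_at_electrode_edges(self, standard_solution):
        sol = standard_solution
        j, i = np.unravel_index(np.argmax(np.abs(sol.grad_e2_x)),
                                sol.grad_e2_x.shape)
        edges = np.asarray(sol.geometry.electrode_edges)
        assert sol.y[j] < 0.2 * sol.geometry.height
        assert np.min(np.abs(sol.x[i] - edges)) < 2e-6

    def test_fom_location_inside_domain(self, standard_solution):
        fom = top_line_fom(standard_solution)
        assert 0.0 < fom.x_location < standard_solution.geometry.domain_width
        assert fom.value > 0.0

    def test_shallow_channel_beats_deep_channel(self, fom_um):
        assert fom_um(25, 40, 10) > fom_um(75, 40, 10)


class TestConvergenceStudy:
    def test_fom_stabilizes_for_reference_geometry(self):
        # 100 um electrodes, 15 um gap, 40 um channel
        geo = ChannelGeometry.from_microns(40, 100, 15)
        table = convergence_study(geo, 2.0, levels=(0, 1, 2))
        assert table["fom"].notna().all()
        assert table["rel_change"].iloc[-1] < 0.02

    def test_requires_three_levels(self):
        geo = ChannelGeometry.from_microns(40, 100, 15)
        with pytest.raises(ValueError):
            convergence_study(geo, 2.0, levels=(0, 1))

    def test_coarse_vs_fine_reported_without_crash(self):
        geo = ChannelGeometry.from_microns(25, 20, 20)
        table = convergence_study(geo, 2.0, levels=(0, 1, 2))
        assert {"mesh_spacing", "fom", "rel_change"} <= set(table.columns)
        assert "monotone" in table.attrs
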