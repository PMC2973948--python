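"""FEM field model: meshing contracts, Laplace accuracy, membrane coupling."""

import numpy as np
import pytest

from tests.conftest import structured_strip_mesh
from vsdassay.errors import (
    ConfigurationError,
    GeometryError,
    LocationError,
    ProtocolError,
    ThresholdUnreachableError,
)
from vsdassay.field import (
    CultureGeometry,
    Electrode,
    StimulusPulse,
    membrane_polarization,
    min_suprathreshold_voltage,
    potential_at,
    solve_laplace,
    triangulate,
)
from vsdassay.membrane import PassiveMembrane


class TestTriangulate:
    def test_unit_square_area_conserved_and_bounded(self, unit_square):
        geom = CultureGeometry(domain=unit_square)
        mesh = triangulate(geom, max_area=0.5)
        areas = mesh.areas()
        assert np.all(areas <= 0.5 + 1e-12)
        assert areas.sum() == pytest.approx(1.0, abs=1e-12)

    def test_halving_max_area_strictly_increases_nodes(self, unit_square):
        geom = CultureGeometry(domain=unit_square)
        ma, prev = 0.5, None
        for _ in range(6):
            n = len(triangulate(geom, max_area=ma).nodes)
            if prev is not None:
                assert n > prev
            prev, ma = n, ma / 2

    def test_refinement_near_electrodes(self, square_bipole_geom):
        mesh = triangulate(square_bipole_geom, max_area=0.02)
        areas = mesh.areas()
        cent = mesh.nodes[mesh.triangles].mean(axis=1)
        near = np.hypot(cent[:, 0] - 0.25, cent[:, 1] - 0.5) < 0.06
        assert areas[near].max() < areas.max()

    def test_cell_overlapping_electrode_rejected(self, unit_square):
        th = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        cell = np.column_stack([0.25 + 0.05 * np.cos(th), 0.5 + 0.05 * np.sin(th)])
        with pytest.raises(GeometryError):
            CultureGeometry(
                domain=unit_square,
                electrodes=[Electrode((0.25, 0.5), 0.03, +1), Electrode((0.75, 0.5), 0.03, -1)],
                cells=[cell],
            )

    def test_self_intersecting_domain_reports_vertex(self):
        bowtie = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(GeometryError):
            CultureGeometry(domain=bowtie)

    def test_single_polarity_rejected(self, unit_square):
        with pytest.raises(GeometryError):
            CultureGeometry(domain=unit_square,
                            electrodes=[Electrode((0.5, 0.5), 0.03, +1)])


class TestSolveLaplace:
    def test_parallel_plate_reproduces_linear_solution_exactly(self):
        mesh = structured_strip_mesh()
        sol = solve_laplace(mesh, amplitude=1.0)
        exact = mesh.nodes[:, 0] - 0.5
        assert np.max(np.abs(sol.phi - exact)) < 1e-9
        assert abs(potential_at(sol, (0.5, 0.37))) < 1e-9
        assert potential_at(sol, (0.25, 0.5)) == pytest.approx(-0.25, abs=1e-9)

    def test_solution_independent_of_conductivity(self):
        mesh = structured_strip_mesh()
        a = solve_laplace(mesh, sigma=1.5).phi
        b = solve_laplace(mesh, sigma=3.0).phi
        assert np.array_equal(a, b) or np.max(np.abs(a - b)) < 1e-12

    def test_missing_polarity_raises_configuration_error(self):
        mesh = structured_strip_mesh()
        mesh.electrode_polarity = {"electrode_0": -1}
        with pytest.raises(ConfigurationError):
            solve_laplace(mesh)

    def test_discrete_maximum_principle(self, square_bipole_geom):
        mesh = triangulate(square_bipole_geom, max_area=0.01)
        sol = solve_laplace(mesh, amplitude=2.0)
        tags = np.asarray(mesh.boundary_tags)
        interior = ~np.isin(tags, list(mesh.electrode_polarity))
        assert sol.phi.max() == pytest.approx(1.0)
        assert sol.phi.min() == pytest.approx(-1.0)
        assert np.all(sol.phi[interior] < 1.0)
        assert np.all(sol.phi[interior] > -1.0)

    def test_bipole_matches_log_potential_closed_form(self):
        # two small discs in a large disc: phi = c ln(r-/r+) + const away from
        # the poles and the outer boundary
        R, a = 25.0, 0.025
        th = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        disc = np.column_stack([R * np.cos(th), R * np.sin(th)])
        geom = CultureGeometry(domain=disc,
                               electrodes=[Electrode((-0.5, 0.0), a, +1),
                                           Electrode((0.5, 0.0), a, -1)])
        sol = solve_laplace(triangulate(geom, max_area=2.0), amplitude=1.0)
        nodes = sol.mesh.nodes
        rp = np.hypot(nodes[:, 0] + 0.5, nodes[:, 1])
        rm = np.hypot(nodes[:, 0] - 0.5, nodes[:, 1])
        rb = R - np.hypot(nodes[:, 0], nodes[:, 1])
        elig = (rp > 5 * a) & (rm > 5 * a) & (rb > 5 * a)
        design = np.column_stack([np.log(rm[elig] / rp[elig]), np.ones(elig.sum())])
        coef, *_ = np.linalg.lstsq(design, sol.phi[elig], rcond=None)
        rel = np.abs(sol.phi[elig] - design @ coef).max() / np.abs(sol.phi[elig]).max()
        assert rel < 0.02

    def test_mesh_refinement_convergence(self, square_bipole_geom):
        probes = [(0.5, 0.5), (0.5, 0.25), (0.35, 0.6)]
        vals = []
        for ma in (0.004, 0.001):
            sol = solve_laplace(triangulate(square_bipole_geom, max_area=ma))
            vals.append([potential_at(sol, p) for p in probes])
        scale = np.abs(np.asarray(vals[1])).max()
        assert np.max(np.abs(np.asarray(vals[0]) - vals[1])) < 0.01 * max(scale, 0.5)

    def test_linearity_in_amplitude(self):
        mesh = structured_strip_mesh(8, 4)
        phi1 = solve_laplace(mesh, amplitude=1.0).phi
        phi3 = solve_laplace(mesh, amplitude=3.0).phi
        assert np.allclose(phi3, 3.0 * phi1, atol=1e-12)


class TestPotentialAt:
    @pytest.fixture()
    def sol(self, square_bipole_geom):
        return solve_laplace(triangulate(square_bipole_geom, max_area=0.02))

    def test_exact_at_nodes(self, sol):
        for i in (0, 7, len(sol.phi) // 2):
            assert potential_at(sol, sol.mesh.nodes[i]) == pytest.approx(sol.phi[i], abs=1e-12)

    def test_centroid_is_mean_of_vertices(self, sol):
        tri = sol.mesh.triangles[len(sol.mesh.triangles) // 3]
        centroid = sol.mesh.nodes[tri].mean(axis=0)
        assert potential_at(sol, centroid) == pytest.approx(sol.phi[tri].mean(), abs=1e-12)

    def test_shared_edge_is_single_valued(self, sol):
        # midpoint of an interior edge: the interpolant is continuous across it
        tri = sol.mesh.triangles[0]
        edge_mid = sol.mesh.nodes[tri[:2]].mean(axis=0)
        expected = sol.phi[tri[:2]].mean()
        assert potential_at(sol, edge_mid) == pytest.approx(expected, abs=1e-12)

    def test_outside_domain_raises(self, sol):
        with pytest.raises(LocationError):
            potential_at(sol, (5.0, 5.0))


class TestMembranePolarization:
    @pytest.fixture()
    def uniform_sol(self):
        return solve_laplace(structured_strip_mesh(30, 15), amplitude=1.0)

    @pytest.fixture()
    def square_cell(self):
        return np.array([[0.4, 0.4], [0.6, 0.4], [0.6, 0.6], [0.4, 0.6]])

    def test_perimeter_reference_drive_is_zero_mean(self, uniform_sol, square_cell, mem):
        pol = membrane_polarization(uniform_sol, square_cell, mem, StimulusPulse(1.0, 5.0))
        assert pol.steady_drive.mean() == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_cell_depolarization_equals_hyperpolarization(
            self, uniform_sol, square_cell, mem):
        pol = membrane_polarization(uniform_sol, square_cell, mem, StimulusPulse(1.0, 5.0))
        assert pol.peak_depolarization == pytest.approx(-pol.peak_hyperpolarization, rel=1e-6)

    def test_long_pulse_reaches_steady_drive(self, uniform_sol, square_cell, mem):
        pulse = StimulusPulse(1.0, 10.0 * mem.tau_ms)
        pol = membrane_polarization(uniform_sol, square_cell, mem, pulse)
        assert pol.peak_depolarization == pytest.approx(pol.steady_drive.max(), rel=0.01)

    def test_response_linear_in_amplitude(self, square_cell, mem):
        mesh = structured_strip_mesh(30, 15)
        pulse = StimulusPulse(1.0, 5.0)
        p1 = membrane_polarization(solve_laplace(mesh, amplitude=1.0), square_cell, mem, pulse)
        p2 = membrane_polarization(solve_laplace(mesh, amplitude=2.0), square_cell, mem, pulse)
        assert np.allclose(p2.dvm, 2.0 * p1.dvm, atol=1e-12)

    def test_bath_reference_uses_absolute_potential(self, uniform_sol, mem):
        # a cell off the midline sits at nonzero phi: the bath-referenced
        # drive is dominated by that offset, the perimeter-referenced is not
        cell = np.array([[0.2, 0.4], [0.3, 0.4], [0.3, 0.6], [0.2, 0.6]])
        bath = membrane_polarization(uniform_sol, cell, mem, StimulusPulse(1.0, 5.0),
                                     reference="bath")
        per = membrane_polarization(uniform_sol, cell, mem, StimulusPulse(1.0, 5.0))
        assert bath.peak_polarization > 3 * per.peak_polarization

    def test_zero_duration_pulse_rejected(self):
        with pytest.raises(ProtocolError):
            StimulusPulse(1.0, 0.0)


class TestMinSuprathresholdVoltage:
    @pytest.fixture()
    def geom_with_cell(self, unit_square):
        th = np.linspace(0, 2 * np.pi, 32, endpoint=False)
        cell = np.column_stack([0.5 + 0.05 * np.cos(th), 0.5 + 0.05 * np.sin(th)])
        return CultureGeometry(
            domain=unit_square,
            electrodes=[Electrode((0.2, 0.5), 0.02, +1), Electrode((0.8, 0.5), 0.02, -1)],
            cells=[cell],
        )

    def test_zero_threshold_returns_lower_search_bound(self, geom_with_cell):
        amp, peaks = min_suprathreshold_voltage(geom_with_cell, threshold=0.0,
                                                max_area=0.01)
        assert amp == pytest.approx(0.01)
        assert peaks.shape == (1,)

    def test_amplitude_scales_inversely_with_threshold(self, geom_with_cell):
        a1, _ = min_suprathreshold_voltage(geom_with_cell, threshold=1.0, max_area=0.01)
        a2, _ = min_suprathreshold_voltage(geom_with_cell, threshold=2.0, max_area=0.01)
        assert a2 == pytest.approx(2.0 * a1, abs=0.03)

    def test_unreachable_threshold_names_limiting_cell(self, geom_with_cell):
        with pytest.raises(ThresholdUnreachableError) as err:
            min_suprathreshold_voltage(geom_with_cell, threshold=1e6, max_area=0.01)
        assert err.value.limiting_cell == 0

    def test_no_cells_rejected(self, square_bipole_geom):
        with pytest.raises(ConfigurationError):
            min_suprathreshold_voltage(square_bipole_geom, threshold=1.0)
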