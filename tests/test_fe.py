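"""Finite-element verification: meshing, patch test, plane-strain
constitutive checks, beam benchmark and invariances."""

import numpy as np
import pytest
from shapely.geometry import Polygon

from femfall import fe


def _square(side=10.0):
    return Polygon([(0, 0), (side, 0), (side, side), (0, side)])


def _uniform_materials(mesh, e=1000.0, nu=0.3):
    return fe.MaterialField(density=np.ones(mesh.n_elements),
                            youngs=np.full(mesh.n_elements, e),
                            poisson=np.full(mesh.n_elements, nu))


def _edge_load(mesh, where, direction, pressure, thickness=1.0):
    """Lump a uniform traction over the nodes selected by ``where``."""
    forces = np.zeros((mesh.n_nodes, 2))
    nodes = np.flatnonzero(where(mesh.nodes))
    spread = mesh.nodes[nodes].max(axis=0) - mesh.nodes[nodes].min(axis=0)
    axis = int(np.argmax(spread))    # the direction the edge runs along
    order = np.argsort(mesh.nodes[nodes, axis])
    nodes = nodes[order]
    segs = np.diff(mesh.nodes[nodes, axis])
    for k, ln in enumerate(segs):
        f = 0.5 * pressure * ln * thickness * np.asarray(direction)
        forces[nodes[k]] += f
        forces[nodes[k + 1]] += f
    total = float(np.linalg.norm(forces.sum(axis=0)))
    return fe.LoadCase(forces=forces, total_force=total, thickness=thickness)


@pytest.fixture(scope="module")
def square_problem():
    mesh = fe.mesh_polygons([_square()], 300)
    mats = _uniform_materials(mesh)
    fixed = np.zeros((mesh.n_nodes, 2), dtype=bool)
    fixed[np.abs(mesh.nodes[:, 0]) < 1e-9, 0] = True
    fixed[np.abs(mesh.nodes[:, 1]) < 1e-9, 1] = True
    bc = fe.BoundaryConditions(fixed=fixed)
    load = _edge_load(mesh, lambda n: np.abs(n[:, 0] - 10.0) < 1e-9,
                      (1.0, 0.0), 2.0)
    return mesh, mats, bc, load


class TestMeshing:
    def test_area_conserved(self):
        mesh = fe.mesh_polygons([_square(1.0)], 100)
        assert mesh.areas().sum() == pytest.approx(1.0, abs=1e-6)
        assert 60 <= mesh.n_elements <= 160

    def test_no_inverted_elements_on_femur(self, one_subject):
        from femfall import morphometry as M
        _, _, scan = one_subject
        pads = M.place_pads(scan)
        mesh = fe.mesh_domain(scan, pads, 2000)
        assert np.all(mesh.areas() > 0)
        assert set(np.unique(mesh.tags)) == {fe.TAG_FEMUR, fe.TAG_TROCH_PAD,
                                             fe.TAG_HEAD_PAD}

    def test_element_count_scales_with_target(self, one_subject):
        from femfall import morphometry as M
        _, _, scan = one_subject
        pads = M.place_pads(scan)
        n1 = fe.mesh_domain(scan, pads, 1500).n_elements
        n2 = fe.mesh_domain(scan, pads, 3000).n_elements
        assert n2 / n1 == pytest.approx(2.0, rel=0.30)

    def test_tiny_target_rejected(self, one_subject):
        from femfall import morphometry as M
        _, _, scan = one_subject
        pads = M.place_pads(scan)
        with pytest.raises(fe.FEError):
            fe.mesh_domain(scan, pads, 100)


class TestMaterials:
    def test_uniform_bmd_gives_uniform_modulus(self, one_subject):
        from femfall import morphometry as M
        from femfall.cohort import ScanRaster
        _, _, scan = one_subject
        flat = ScanRaster(np.where(scan.mask, 0.8, 0.0), scan.mask,
                          scan.pixel_dx, scan.pixel_dy)
        pads = M.place_pads(flat)
        mesh = fe.mesh_domain(flat, pads, 1500)
        mats = fe.assign_materials(mesh, flat)
        femur = mesh.tags == fe.TAG_FEMUR
        # away from the boundary the bilinear sample is exactly the map value
        interior = femur & np.isclose(mats.density, 0.8, atol=1e-9)
        assert interior.sum() > 0.6 * femur.sum()
        assert np.allclose(mats.youngs[interior],
                           6850.0 * 0.8 ** 1.49, rtol=1e-9)
        assert np.all(mats.poisson[~femur] == fe.PMMA_NU)
        assert np.all(mats.youngs[~femur] == fe.PMMA_E)

    def test_zero_density_floored(self, one_subject):
        from femfall import morphometry as M
        from femfall.cohort import ScanRaster
        _, _, scan = one_subject
        empty = ScanRaster(np.zeros_like(scan.bmd_map), scan.mask,
                           scan.pixel_dx, scan.pixel_dy)
        pads = M.place_pads(scan)
        mesh = fe.mesh_domain(scan, pads, 1500)
        mats = fe.assign_materials(mesh, empty)
        femur = mesh.tags == fe.TAG_FEMUR
        assert np.all(mats.youngs[femur] == 10.0)

    def test_cohort_tissue_moduli_bracket_published_means(self, small_attribute_table):
        assert 2.8 <= small_attribute_table["TBE"].mean() <= 4.5
        assert 9.0 <= small_attribute_table["CTE"].mean() <= 13.0


class TestSolver:
    def test_patch_uniform_stress_exact(self, square_problem):
        mesh, mats, bc, load = square_problem
        sol = fe.solve(mesh, mats, bc, load)
        assert np.allclose(sol.stress[:, 0], 2.0, atol=1e-9)
        assert np.allclose(sol.stress[:, 1], 0.0, atol=1e-9)
        assert np.allclose(sol.stress[:, 2], 0.0, atol=1e-9)

    def test_plane_strain_von_mises_closed_form(self, square_problem):
        mesh, mats, bc, load = square_problem
        sol = fe.solve(mesh, mats, bc, load)
        expected = 2.0 * np.sqrt(0.5 * (1 + 0.09 + 0.49))
        assert np.allclose(sol.von_mises, expected, atol=1e-9)
        assert np.allclose(sol.stress_zz, 0.3 * 2.0, atol=1e-9)

    def test_equilibrium_residual(self, square_problem):
        mesh, mats, bc, load = square_problem
        sol = fe.solve(mesh, mats, bc, load)
        assert sol.equilibrium_residual < 1e-6

    def test_linearity_in_load(self, square_problem):
        mesh, mats, bc, load = square_problem
        sol1 = fe.solve(mesh, mats, bc, load)
        load2 = fe.LoadCase(forces=2 * load.forces, total_force=2 * load.total_force,
                            thickness=load.thickness)
        sol2 = fe.solve(mesh, mats, bc, load2)
        assert np.allclose(sol2.displacements, 2 * sol1.displacements,
                           rtol=1e-10, atol=1e-14)

    def test_zero_load_zero_displacement(self, square_problem):
        mesh, mats, bc, _ = square_problem
        load0 = fe.LoadCase(forces=np.zeros((mesh.n_nodes, 2)),
                            total_force=0.0, thickness=1.0)
        sol = fe.solve(mesh, mats, bc, load0)
        assert np.allclose(sol.displacements, 0.0)

    def test_unconstrained_system_rejected(self, square_problem):
        mesh, mats, _, load = square_problem
        bc = fe.BoundaryConditions(fixed=np.zeros((mesh.n_nodes, 2), dtype=bool))
        with pytest.raises(fe.FEError):
            fe.solve(mesh, mats, bc, load)

    def test_rigid_translation_objectivity(self, square_problem):
        mesh, mats, bc, load = square_problem
        sol = fe.solve(mesh, mats, bc, load)
        shifted = fe.Mesh2D(nodes=mesh.nodes + np.array([37.0, -12.0]),
                            elements=mesh.elements.copy(),
                            tags=mesh.tags.copy())
        sol2 = fe.solve(shifted, mats, bc, load)
        assert np.allclose(sol2.stress, sol.stress, atol=1e-9)

    def test_cantilever_matches_beam_theory(self):
        """Tip deflection of a slender cantilever within 10% of the
        Euler-Bernoulli prediction (plane-strain effective modulus)."""
        L, h, t = 100.0, 10.0, 1.0
        mesh = fe.mesh_polygons([Polygon([(0, 0), (L, 0), (L, h), (0, h)])], 2500)
        e, nu = 10000.0, 0.3
        mats = _uniform_materials(mesh, e, nu)
        fixed = np.zeros((mesh.n_nodes, 2), dtype=bool)
        fixed[np.abs(mesh.nodes[:, 0]) < 1e-9, :] = True
        bc = fe.BoundaryConditions(fixed=fixed)
        P = 10.0
        load = _edge_load(mesh, lambda n: np.abs(n[:, 0] - L) < 1e-9,
                          (0.0, -1.0), P / h, t)
        sol = fe.solve(mesh, mats, bc, load)
        tip = np.flatnonzero((np.abs(mesh.nodes[:, 0] - L) < 1e-9)
                             & (np.abs(mesh.nodes[:, 1] - h / 2) < h / 2))
        delta = -sol.displacements[tip, 1].mean()
        e_eff = e / (1 - nu ** 2)
        inertia = t * h ** 3 / 12.0
        expected = P * L ** 3 / (3 * e_eff * inertia)
        assert delta == pytest.approx(expected, rel=0.10)


@pytest.fixture(scope="module")
def femur_solution(one_subject):
    from femfall import morphometry as M
    _, _, scan = one_subject
    pads = M.place_pads(scan)
    mesh = fe.mesh_domain(scan, pads, 2000)
    mats = fe.assign_materials(mesh, scan)
    bc = fe.apply_constraints(mesh, pads)
    load = fe.apply_load(mesh, 6.5, pads)
    sol = fe.solve(mesh, mats, bc, load)
    return mesh, mats, bc, load, sol, pads


class TestFemurBoundaryConditions:
    def test_constraint_sets_nonempty(self, femur_solution):
        _, _, bc, _, _, _ = femur_solution
        assert len(bc.distal_nodes) > 0
        assert len(bc.head_pad_nodes) > 0

    def test_head_pad_moves_vertically(self, femur_solution):
        _, _, bc, _, sol, _ = femur_solution
        uy = sol.displacements[bc.head_pad_nodes, 1]
        assert np.any(np.abs(uy) > 0)
        assert np.allclose(sol.displacements[bc.head_pad_nodes, 0], 0.0)

    def test_total_load_equals_pressure_times_pad_area(self, femur_solution):
        _, _, _, load, _, pads = femur_solution
        resultant = np.linalg.norm(load.forces.sum(axis=0))
        assert resultant == pytest.approx(6.5 * pads.b * pads.t, rel=1e-9)

    def test_equilibrium_on_femur(self, femur_solution):
        _, _, _, _, sol, _ = femur_solution
        assert sol.equilibrium_residual < 1e-6

    def test_releasing_head_pad_increases_medial_motion(self, one_subject):
        from femfall import morphometry as M
        _, _, scan = one_subject
        pads = M.place_pads(scan)
        mesh = fe.mesh_domain(scan, pads, 2000)
        mats = fe.assign_materials(mesh, scan)
        bc = fe.apply_constraints(mesh, pads)
        load = fe.apply_load(mesh, 6.5, pads)
        sol = fe.solve(mesh, mats, bc, load)
        free = fe.BoundaryConditions(fixed=bc.fixed.copy())
        free.fixed[bc.head_pad_nodes, 0] = False
        sol2 = fe.solve(mesh, mats, free, load)
        med = np.abs(sol2.displacements[bc.head_pad_nodes, 0]).max()
        assert med > np.abs(sol.displacements[bc.head_pad_nodes, 0]).max()


class TestVtkDump:
    def test_legacy_ascii_round_trip(self, tmp_path, square_problem):
        mesh, mats, bc, load = square_problem
        sol = fe.solve(mesh, mats, bc, load)
        path = tmp_path / "sol.vtk"
        fe.write_vtk(sol, path, mats)
        text = path.read_text().splitlines()
        assert text[0].startswith("# vtk DataFile")
        assert f"POINTS {mesh.n_nodes} float" in text
        assert f"CELL_TYPES {mesh.n_elements}" in text
        assert "SCALARS von_mises_mpa float 1" in text
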