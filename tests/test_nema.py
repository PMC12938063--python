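"""Inverse membrane equilibrium solver: Laplace-law oracles, linearity,
frame invariance, and force balance."""

import numpy as np
import pytest

from aaastress.geometry import SurfaceMesh
from aaastress.nema import (LoadCase, MembraneElement, SolverError,
                            assemble_equilibrium, convert_pressure,
                            element_basis, principal_stresses, solve_stress,
                            vertex_tangent_frames)
from aaastress.phantom import make_cylinder_mesh, make_sphere_mesh


def mid_elements(mesh, lo, hi):
    z = mesh.vertices[mesh.triangles].mean(axis=1)[:, 2]
    return (z > lo) & (z < hi)


# ---------------------------------------------------------------------------
# Pressure conversion and load case
# ---------------------------------------------------------------------------

def test_convert_pressure():
    assert convert_pressure(0.0) == 0.0
    assert convert_pressure(93.3) == pytest.approx(1.2439, abs=1e-4)
    assert convert_pressure(750.062) == pytest.approx(10.0, rel=1e-5)
    with pytest.raises(ValueError):
        convert_pressure(-1.0)


def test_load_case_units():
    load = LoadCase(pressure_mmHg=93.3, thickness_mm=1.5)
    assert load.thickness_h == pytest.approx(0.15)
    assert load.pressure_internal == pytest.approx(1.2439, abs=1e-4)
    with pytest.raises(ValueError):
        LoadCase(pressure_mmHg=93.3, thickness_mm=0.0)


# ---------------------------------------------------------------------------
# Element basis
# ---------------------------------------------------------------------------

def test_element_basis_right_isoceles():
    mesh = SurfaceMesh(
        vertices=np.array([[0., 0., 0.], [1., 0., 0.], [0., 1., 0.]]),
        triangles=np.array([[0, 1, 2]]))
    elem = element_basis(mesh, 0)
    np.testing.assert_allclose(elem.metric, np.eye(2), atol=1e-12)
    assert elem.g_det == pytest.approx(1.0)


def test_gdet_equals_four_area_squared(sphere_mesh):
    for idx in (0, 100, 500):
        elem = element_basis(sphere_mesh, idx)
        assert elem.g_det == pytest.approx((2 * elem.area) ** 2, rel=1e-10)
        assert abs(elem.normal @ elem.g1) < 1e-12
        assert abs(elem.normal @ elem.g2) < 1e-12


def test_metric_invariant_under_rotation(sphere_mesh):
    th = 0.9
    R = np.array([[1, 0, 0], [0, np.cos(th), -np.sin(th)],
                  [0, np.sin(th), np.cos(th)]])
    rotated = SurfaceMesh(vertices=sphere_mesh.vertices @ R.T,
                          triangles=sphere_mesh.triangles)
    for idx in (3, 77):
        np.testing.assert_allclose(element_basis(rotated, idx).metric,
                                   element_basis(sphere_mesh, idx).metric,
                                   rtol=1e-9, atol=1e-12)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def test_zero_pressure_gives_zero_stress(load_case):
    mesh = make_cylinder_mesh(1.5, 6.0, 24, 13)
    field = solve_stress(mesh, LoadCase(pressure_mmHg=0.0,
                                        thickness_mm=1.5))
    assert np.max(np.abs(field.principal_1)) < 1e-10


def test_system_matrix_independent_of_stress_state(load_case):
    """Fixed-configuration equilibrium: A depends only on geometry/load,
    so two assemblies agree exactly."""
    mesh = make_cylinder_mesh(1.5, 3.0, 16, 7)
    A1, b1, _ = assemble_equilibrium(mesh, load_case)
    A2, b2, _ = assemble_equilibrium(mesh, load_case)
    assert (A1 != A2).nnz == 0
    np.testing.assert_array_equal(b1, b2)


def test_closed_form_cylinder_satisfies_discrete_equilibrium(load_case):
    """Plugging hoop = pR/h, axial = shear = 0 into the assembled system
    leaves an interior residual far below the load norm."""
    R, h = 1.5, load_case.thickness_h
    mesh = make_cylinder_mesh(R, 6.0, 64, 49)
    A, b, info = assemble_equilibrium(mesh, load_case)
    hoop = load_case.pressure_internal * R / h
    f1, f2, _ = vertex_tangent_frames(mesh)
    x = np.empty(3 * mesh.n_vertices)
    for v in range(mesh.n_vertices):
        pos = mesh.vertices[v]
        e_theta = np.array([-pos[1], pos[0], 0.0])
        e_theta /= np.linalg.norm(e_theta)
        T = hoop * np.outer(e_theta, e_theta)
        # unknown vector stores the shear scaled by sqrt(2) (Frobenius norm)
        x[3 * v:3 * v + 3] = (f1[v] @ T @ f1[v],
                              np.sqrt(2.0) * (f1[v] @ T @ f2[v]),
                              f2[v] @ T @ f2[v])
    residual = np.linalg.norm(A @ x - b) / np.linalg.norm(b)
    assert residual < 0.02


def test_assembly_requires_boundary_information(load_case):
    mesh = make_cylinder_mesh(1.0, 2.0, 16, 5)
    unlabeled = SurfaceMesh(vertices=mesh.vertices,
                            triangles=mesh.triangles)
    with pytest.raises(ValueError):
        assemble_equilibrium(unlabeled, load_case)


# ---------------------------------------------------------------------------
# Solutions
# ---------------------------------------------------------------------------

def test_cylinder_matches_laplace_hoop(cylinder_mesh, load_case):
    """First principal stress at mid-length within 5% of pR/h; second
    (axial) principal stress near zero for the open tube."""
    field = solve_stress(cylinder_mesh, load_case)
    expected = load_case.pressure_internal * 1.5 / load_case.thickness_h
    mid = mid_elements(cylinder_mesh, 2.0, 4.0)
    p1 = field.principal_1[mid]
    assert np.abs(p1.mean() - expected) / expected < 0.05
    assert np.max(np.abs(p1 - expected)) / expected < 0.05
    assert np.max(np.abs(field.principal_2[mid])) < 0.05 * expected


def test_sphere_matches_laplace_biaxial(sphere_mesh, load_case):
    field = solve_stress(sphere_mesh, load_case)
    expected = load_case.pressure_internal * 1.5 / (
        2 * load_case.thickness_h)
    for p in (field.principal_1, field.principal_2):
        assert np.abs(np.mean(p) - expected) / expected < 0.05


def test_stress_scales_linearly_with_pressure_and_thickness(load_case):
    mesh = make_cylinder_mesh(1.5, 6.0, 24, 13)
    base = solve_stress(mesh, load_case)
    double_p = solve_stress(mesh, LoadCase(2 * load_case.pressure_mmHg,
                                           load_case.thickness_mm))
    double_h = solve_stress(mesh, LoadCase(load_case.pressure_mmHg,
                                           2 * load_case.thickness_mm))
    np.testing.assert_allclose(double_p.principal_1, 2 * base.principal_1,
                               rtol=1e-8)
    np.testing.assert_allclose(double_h.principal_1, 0.5 * base.principal_1,
                               rtol=1e-8)


def test_mesh_refinement_converges_monotonically(load_case):
    errors = []
    for n_theta, n_z in [(16, 9), (32, 17), (64, 33)]:
        mesh = make_cylinder_mesh(1.5, 6.0, n_theta, n_z)
        field = solve_stress(mesh, load_case)
        expected = load_case.pressure_internal * 1.5 / load_case.thickness_h
        mid = mid_elements(mesh, 2.0, 4.0)
        errors.append(abs(field.principal_1[mid].mean() - expected)
                      / expected)
    assert errors[0] > errors[1] > errors[2]


def test_frame_invariance_of_principal_stresses(load_case):
    mesh = make_cylinder_mesh(1.5, 4.0, 24, 13)
    base = solve_stress(mesh, load_case)
    rng = np.random.default_rng(5)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    rotated_mesh = SurfaceMesh(vertices=mesh.vertices @ q.T,
                               triangles=mesh.triangles,
                               proximal_ring=mesh.proximal_ring,
                               distal_ring=mesh.distal_ring)
    rotated = solve_stress(rotated_mesh, load_case)
    np.testing.assert_allclose(rotated.principal_1, base.principal_1,
                               rtol=1e-6, atol=1e-8)


def test_global_force_balance(cylinder_mesh, load_case):
    """Boundary reactions balance the applied pressure load."""
    field = solve_stress(cylinder_mesh, load_case)
    assert field.diagnostics["force_balance_error"] < 1e-6


def test_newton_wrapper_converges_in_one_step(load_case):
    mesh = make_cylinder_mesh(1.5, 3.0, 16, 9)
    one = solve_stress(mesh, load_case, newton_iters=1)
    three = solve_stress(mesh, load_case, newton_iters=3)
    np.testing.assert_allclose(three.principal_1, one.principal_1,
                               rtol=1e-9)


# ---------------------------------------------------------------------------
# Principal stresses
# ---------------------------------------------------------------------------

def _orthonormal_element():
    mesh = SurfaceMesh(
        vertices=np.array([[0., 0., 0.], [1., 0., 0.], [0., 1., 0.]]),
        triangles=np.array([[0, 1, 2]]))
    return element_basis(mesh, 0)


def test_principal_isotropic_and_uniaxial():
    elem = _orthonormal_element()
    assert principal_stresses([3.0, 0.0, 3.0], elem) == \
        pytest.approx((3.0, 3.0))
    assert principal_stresses([5.0, 0.0, 0.0], elem) == \
        pytest.approx((5.0, 0.0), abs=1e-12)


def test_principal_matches_eigensolver_oracle():
    elem = _orthonormal_element()
    rng = np.random.default_rng(11)
    for _ in range(20):
        s11, s12, s22 = rng.normal(size=3)
        p1, p2 = principal_stresses([s11, s12, s22], elem)
        eig = np.sort(np.linalg.eigvalsh(
            np.array([[s11, s12], [s12, s22]])))[::-1]
        np.testing.assert_allclose([p1, p2], eig, atol=1e-10)
        assert p1 >= p2


def test_global_tensor_annihilates_normal(cylinder_mesh, load_case):
    field = solve_stress(cylinder_mesh, load_case)
    from aaastress.geometry import element_geometry

    _, normals, _ = element_geometry(cylinder_mesh)
    along_normal = np.einsum("fij,fj->fi", field.global_tensor, normals)
    scale = np.abs(field.principal_1).max()
    assert np.max(np.linalg.norm(along_normal, axis=1)) < 1e-8 * scale
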