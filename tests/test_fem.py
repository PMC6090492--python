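import numpy as np
import pytest
import scipy.sparse.linalg as spla

from constructsim import (
    MaterialModel,
    assemble_stiffness,
    build_mesh,
    compute_strain,
    solve_displacements,
)
from constructsim.fem import _free_dof_mask


def _solve_with_prescribed_boundary(mesh, material, u_prescribed, boundary):
    """Solve K u = 0 with displacements prescribed on the given nodes."""
    K = assemble_stiffness(mesh, material).tocsr()
    free = np.ones(3 * mesh.n_nodes, bool)
    free[(3 * boundary[:, None] + np.arange(3)).ravel()] = False
    u = u_prescribed.ravel().copy()
    rhs = -(K[free][:, ~free] @ u[~free])
    u[free] = spla.spsolve(K[free][:, free].tocsc(), rhs)
    return u.reshape(-1, 3)


def test_material_validation():
    with pytest.raises(ValueError, match="incompressible"):
        MaterialModel(poisson_ratio=0.5)
    with pytest.raises(ValueError):
        MaterialModel(elastic_modulus=-1.0)
    m = MaterialModel()
    assert m.elastic_modulus == 100e3
    assert m.poisson_ratio == 0.45
    assert m.density == 1100.0


def test_element_has_exactly_six_rigid_body_modes(unit_element, material):
    K = assemble_stiffness(unit_element, material).toarray()
    w = np.linalg.eigvalsh(K)
    assert np.all(np.abs(w[:6]) < 1e-9 * w[-1])
    assert w[6] > 1e-6 * w[-1]


def test_uniform_translation_gives_zero_internal_force(unit_element, material):
    K = assemble_stiffness(unit_element, material)
    for d in range(3):
        u = np.zeros((unit_element.n_nodes, 3))
        u[:, d] = 1e-3
        f = K @ u.ravel()
        assert np.abs(f).max() < 1e-12 * np.abs(K.data).max()


def test_stiffness_symmetric_and_constrained_spd(material):
    mesh = build_mesh((0.003, 0.002, 0.002), 0.001)
    K = assemble_stiffness(mesh, material)
    assert abs(K - K.T).max() == 0.0
    free = _free_dof_mask(mesh.n_nodes, mesh.fixed_node_set)
    Kff = K.toarray()[np.ix_(free, free)]
    assert np.linalg.eigvalsh(Kff).min() > 0


def test_patch_test_constant_strain(material):
    """A linear displacement field imposed on the boundary is reproduced in
    the interior and yields the exact constant strain."""
    mesh = build_mesh((0.002, 0.002, 0.002), 0.001)
    A = np.array([[1e-3, 2e-4, -1e-4], [2e-4, -5e-4, 3e-4], [-1e-4, 3e-4, 4e-4]])
    u_exact = mesh.node_coords @ A.T
    c = mesh.node_coords
    eps = 1e-12
    boundary = np.flatnonzero(
        (c[:, 0] < eps) | (c[:, 0] > 0.002 - eps)
        | (c[:, 1] < eps) | (c[:, 1] > 0.002 - eps)
        | (c[:, 2] < eps) | (c[:, 2] > 0.002 - eps)
    )
    u = _solve_with_prescribed_boundary(mesh, material, u_exact, boundary)
    assert np.abs(u - u_exact).max() < 1e-10 * np.abs(u_exact).max()
    field = compute_strain(mesh, u)
    eps_exact = 0.5 * (A + A.T)
    assert np.abs(field.tensors - eps_exact).max() < 1e-10


def test_uniaxial_bar_matches_closed_form(bar_mesh):
    """Clamped-end bar under uniform end traction: tip displacement sigma*L/E
    (Poisson ratio zero eliminates lateral coupling)."""
    mat = MaterialModel(poisson_ratio=0.0)
    K = assemble_stiffness(bar_mesh, mat)
    sigma, L = 100.0, 0.010
    f = np.zeros((bar_mesh.n_nodes, 3))
    tip = np.flatnonzero(bar_mesh.node_coords[:, 0] > L - 1e-12)
    f[tip, 0] = sigma * 0.001 * 0.001 / len(tip)
    fixed = np.flatnonzero(bar_mesh.node_coords[:, 0] < 1e-12)
    u = solve_displacements(K, f, fixed)
    expected = sigma * L / mat.elastic_modulus
    assert np.abs(u[tip, 0] - expected).max() < 1e-3 * expected
    # interior displacement is linear in x
    assert np.allclose(u[:, 0], sigma * bar_mesh.node_coords[:, 0] / mat.elastic_modulus,
                       rtol=1e-10, atol=1e-18)


def test_zero_force_zero_displacement(bar_mesh, material):
    K = assemble_stiffness(bar_mesh, material)
    fixed = np.flatnonzero(bar_mesh.node_coords[:, 0] < 1e-12)
    u = solve_displacements(K, np.zeros((bar_mesh.n_nodes, 3)), fixed)
    assert np.all(u == 0.0)


def test_both_ends_fixed_stay_fixed(bar_mesh, material):
    """Equal-and-opposite end loads with both faces clamped leave the clamped
    nodes exactly at zero displacement."""
    K = assemble_stiffness(bar_mesh, material)
    c = bar_mesh.node_coords
    f = np.zeros((bar_mesh.n_nodes, 3))
    f[c[:, 0] < 1e-12, 0] = -1e-6
    f[c[:, 0] > 0.010 - 1e-12, 0] = 1e-6
    u = solve_displacements(K, f, bar_mesh.fixed_node_set)
    assert np.all(u[bar_mesh.fixed_node_set] == 0.0)


def test_empty_fixed_set_reports_insufficient_constraints(bar_mesh, material):
    K = assemble_stiffness(bar_mesh, material)
    with pytest.raises(ValueError, match="insufficient constraints"):
        solve_displacements(K, np.zeros((bar_mesh.n_nodes, 3)), np.array([], int))


class TestStrainRecovery:
    def test_uniform_stretch(self, construct_mesh):
        alpha = 1e-3
        u = np.zeros((construct_mesh.n_nodes, 3))
        u[:, 0] = alpha * construct_mesh.node_coords[:, 0]
        field = compute_strain(construct_mesh, u)
        expected = np.zeros((3, 3))
        expected[0, 0] = alpha
        assert np.abs(field.tensors - expected).max() < 1e-15

    def test_simple_shear(self, bar_mesh):
        gamma = 2e-3
        u = np.zeros((bar_mesh.n_nodes, 3))
        u[:, 0] = gamma * bar_mesh.node_coords[:, 1]
        field = compute_strain(bar_mesh, u)
        assert np.allclose(field.tensors[:, 0, 1], gamma / 2, atol=1e-15)
        assert np.abs(field.tensors[:, 0, 0]).max() < 1e-15

    def test_small_rotation_strain_second_order(self, unit_element):
        theta = 1e-3
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1.0],
            ]
        )
        u = unit_element.node_coords @ R.T - unit_element.node_coords
        field = compute_strain(unit_element, u)
        assert np.abs(field.tensors).max() < theta**2

    def test_inverted_element_reported(self, unit_element):
        u = np.zeros((unit_element.n_nodes, 3))
        u[:, 0] = -2.0 * unit_element.node_coords[:, 0]  # folds the cube
        with pytest.raises(ValueError, match="element 0"):
            compute_strain(unit_element, u, node_coords=unit_element.node_coords + u)


def test_bar_refinement_consistent(material):
    """Tip displacement of the fully-clamped-end bar changes by little under
    mesh refinement (the coarse answer is already converged to ~1%)."""
    tips = []
    for h in (1e-3, 0.5e-3):
        mesh = build_mesh((0.010, 0.002, 0.002), h)
        K = assemble_stiffness(mesh, material)
        c = mesh.node_coords
        tip = np.flatnonzero(c[:, 0] > 0.010 - 1e-12)
        f = np.zeros((mesh.n_nodes, 3))
        f[tip, 0] = 1e-6 / len(tip)
        fixed = np.flatnonzero(c[:, 0] < 1e-12)
        u = solve_displacements(K, f, fixed)
        tips.append(u[tip, 0].mean())
    assert abs(tips[1] - tips[0]) < 0.05 * abs(tips[1])
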