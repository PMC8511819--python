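"""FE solver verification: element oracle, patch test, closed forms,
convergence, equilibrium."""

import numpy as np
import pytest
import scipy.sparse.linalg

import fracenv as fe
from fracenv.elasticity import (
    LoadCase,
    SolverError,
    assemble_stiffness,
    max_von_mises_by_part,
    nodes_on_plane,
    solve,
    von_mises,
)
from fracenv.meshmat import MaterialField, TetMesh
from fracenv.volume import BONE, GAP


def make_mats(mesh, E=10_000.0, nu=0.0):
    m = mesh.n_elements
    return MaterialField(
        np.full(m, float(E)),
        np.full(m, float(nu)),
        np.full(m, np.nan),
        np.full(m, 1, dtype=np.int8),
    )


def bar_mesh(n=(2, 2, 10), size=(10.0, 10.0, 100.0), order=1):
    labels = np.full(n, BONE, dtype=int)
    spacing = tuple(s / c for s, c in zip(size, n))
    return fe.voxels_to_tets(labels, spacing, order=order)


def single_tet_stiffness_oracle(coords, E, nu):
    """Independent TET4 element stiffness via shape-coefficient solve.

    Shape functions N_i = a_i + b_i x + c_i y + d_i z found by inverting the
    4x4 Vandermonde-type system; K = V * B^T C B assembled entry-wise.
    """
    M = np.hstack([np.ones((4, 1)), coords])
    coeff = np.linalg.inv(M)  # rows: a, b, c, d; columns: nodes
    V = abs(np.linalg.det(M)) / 6.0
    B = np.zeros((6, 12))
    for i in range(4):
        b, c, d = coeff[1, i], coeff[2, i], coeff[3, i]
        B[:, 3 * i: 3 * i + 3] = np.array(
            [
                [b, 0, 0],
                [0, c, 0],
                [0, 0, d],
                [c, b, 0],
                [0, d, c],
                [d, 0, b],
            ]
        )
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.diag([lam + 2 * mu] * 3 + [mu] * 3)
    C[:3, :3] += lam * (1 - np.eye(3))
    return V * B.T @ C @ B


def test_single_tet4_matches_independent_element_oracle():
    coords = np.array(
        [[0.0, 0, 0], [1.2, 0.1, 0], [0.3, 1.5, 0.2], [0.1, 0.2, 1.1]]
    )
    mesh = TetMesh(
        nodes=coords,
        elements=np.array([[0, 1, 2, 3]]),
        element_part=np.array([BONE]),
        order=1,
    )
    for E, nu in ((1.0, 0.0), (250.0, 0.3)):
        K = assemble_stiffness(mesh, make_mats(mesh, E, nu)).toarray()
        Ko = single_tet_stiffness_oracle(coords, E, nu)
        assert np.allclose(K, Ko, atol=1e-12 * max(1.0, abs(Ko).max()))


def test_rigid_translation_is_in_null_space():
    mesh = bar_mesh(n=(2, 2, 3), size=(2, 2, 3))
    K = assemble_stiffness(mesh, make_mats(mesh, 500.0, 0.3))
    t = np.tile([1.0, -2.0, 0.5], mesh.n_nodes)
    assert np.abs(K @ t).max() <= 1e-10 * np.abs(K.data).max()


def test_stiffness_is_linear_in_modulus():
    mesh = bar_mesh(n=(2, 2, 2), size=(2, 2, 2))
    K1 = assemble_stiffness(mesh, make_mats(mesh, 100.0, 0.25))
    K2 = assemble_stiffness(mesh, make_mats(mesh, 200.0, 0.25))
    assert np.allclose((2 * K1 - K2).data, 0.0, atol=1e-9)


def test_inverted_element_is_named():
    coords = np.array(
        [[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]]
    )
    mesh = TetMesh(
        nodes=coords,
        elements=np.array([[0, 2, 1, 3]]),  # negative volume ordering
        element_part=np.array([BONE]),
        order=1,
    )
    with pytest.raises(SolverError, match="element 0"):
        assemble_stiffness(mesh, make_mats(mesh))


@pytest.mark.parametrize("order", [1, 2])
def test_uniaxial_bar_closed_form_with_consistent_load(order):
    """u = FL/EA: L=100 mm, A=100 mm^2, E=10^4 MPa, F=1000 N -> 0.1 mm."""
    mesh = bar_mesh(order=order)
    mats = make_mats(mesh, E=10_000.0, nu=0.0)
    K = assemble_stiffness(mesh, mats)
    lc = LoadCase(
        fixed_nodes=nodes_on_plane(mesh, 2, 0.0),
        load_nodes=nodes_on_plane(mesh, 2, 100.0),
        force=(0.0, 0.0, 1000.0),
        distribution="consistent",
    )
    sol = solve(K, lc, mesh, mats)
    tip = sol.displacement[nodes_on_plane(mesh, 2, 100.0), 2]
    assert np.abs(tip - 0.1).max() <= 1e-10 * 0.1
    assert sol.strain[:, 2] == pytest.approx(1e-3, rel=1e-9)
    assert sol.stress[:, 2] == pytest.approx(10.0, rel=1e-9)
    assert sol.diagnostics["equilibrium_rel"] <= 1e-6


def test_zero_force_gives_zero_displacement():
    mesh = bar_mesh(n=(2, 2, 4), size=(2, 2, 4))
    mats = make_mats(mesh)
    lc = LoadCase(
        fixed_nodes=nodes_on_plane(mesh, 2, 0.0),
        load_nodes=nodes_on_plane(mesh, 2, 4.0),
        force=(0.0, 0.0, 0.0),
    )
    sol = solve(assemble_stiffness(mesh, mats), lc, mesh, mats)
    assert np.all(sol.displacement == 0.0)
    assert np.all(sol.von_mises == 0.0)


@pytest.mark.parametrize("order", [1, 2])
def test_patch_test_reproduces_uniform_strain_exactly(order):
    mesh = bar_mesh(n=(3, 3, 3), size=(3, 3, 3), order=order)
    A = np.array(
        [
            [1e-3, 4e-4, 2e-4],
            [3e-4, -5e-4, 6e-4],
            [2e-4, 1e-4, 7e-4],
        ]
    )
    u_exact = mesh.nodes @ A.T
    nb = mesh.nodes
    on_boundary = (
        (np.abs(nb - nb.min(0)) < 1e-12) | (np.abs(nb - nb.max(0)) < 1e-12)
    ).any(axis=1)
    fixed = np.flatnonzero(on_boundary)
    mats = make_mats(mesh, E=123.0, nu=0.3)
    lc = LoadCase(
        fixed_nodes=fixed,
        load_nodes=np.array([], dtype=int),
        force=(0, 0, 0),
        fixed_values=u_exact[fixed],
    )
    sol = solve(assemble_stiffness(mesh, mats), lc, mesh, mats)
    assert np.abs(sol.displacement - u_exact).max() <= 1e-12
    eps = 0.5 * (A + A.T)
    voigt = np.array(
        [eps[0, 0], eps[1, 1], eps[2, 2], 2 * eps[0, 1], 2 * eps[1, 2],
         2 * eps[0, 2]]
    )
    assert np.abs(sol.strain - voigt).max() <= 1e-12


def _dirichlet_error_for_harmonic_field(n, order):
    """Max nodal error for u_z = sin(kx) cosh(ky) (zero body force)."""
    k = np.pi / 10.0
    labels = np.full((n, n, n), BONE, dtype=int)
    mesh = fe.voxels_to_tets(labels, (10.0 / n,) * 3, order=order)
    u_exact = np.zeros_like(mesh.nodes)
    u_exact[:, 2] = 1e-3 * np.sin(k * mesh.nodes[:, 0]) * np.cosh(
        k * mesh.nodes[:, 1]
    )
    nb = mesh.nodes
    on_boundary = (
        (np.abs(nb - nb.min(0)) < 1e-12) | (np.abs(nb - nb.max(0)) < 1e-12)
    ).any(axis=1)
    fixed = np.flatnonzero(on_boundary)
    mats = make_mats(mesh, E=1000.0, nu=0.3)
    lc = LoadCase(
        fixed_nodes=fixed,
        load_nodes=np.array([], dtype=int),
        force=(0, 0, 0),
        fixed_values=u_exact[fixed],
    )
    sol = solve(assemble_stiffness(mesh, mats), lc, mesh, mats)
    return np.abs(sol.displacement - u_exact).max()


def test_tet4_converges_at_second_order_to_analytic_field():
    errs = [_dirichlet_error_for_harmonic_field(n, 1) for n in (4, 8, 16)]
    rates = [np.log2(errs[i] / errs[i + 1]) for i in range(2)]
    assert errs[0] > errs[1] > errs[2]
    assert min(rates) > 1.5  # observed ~1.8-1.9


def test_tet10_is_far_more_accurate_than_tet4_at_same_mesh():
    e4 = _dirichlet_error_for_harmonic_field(4, 1)
    e10 = _dirichlet_error_for_harmonic_field(4, 2)
    assert e10 < e4 / 5


def test_underconstrained_system_raises():
    mesh = bar_mesh(n=(2, 2, 3), size=(2, 2, 3))
    mats = make_mats(mesh)
    lc = LoadCase(
        fixed_nodes=np.array([0]),  # a single point cannot fix rotations
        load_nodes=nodes_on_plane(mesh, 2, 3.0),
        force=(10.0, 0.0, 0.0),
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with pytest.raises(SolverError):
            solve(assemble_stiffness(mesh, mats), lc, mesh, mats)


def test_von_mises_closed_forms():
    assert von_mises(np.diag([100.0, 0, 0])) == pytest.approx(100.0)
    assert von_mises(np.diag([-50.0, -50.0, -50.0])) == pytest.approx(
        0.0, abs=1e-12
    )
    shear = np.zeros((3, 3))
    shear[0, 1] = shear[1, 0] = 10.0
    assert von_mises(shear) == pytest.approx(10.0 * np.sqrt(3.0))
    # Voigt form agrees with the tensor form
    assert von_mises(np.array([0, 0, 0, 10.0, 0, 0])) == pytest.approx(
        10.0 * np.sqrt(3.0)
    )


def test_max_von_mises_by_part_matches_linear_scan():
    mesh = bar_mesh(n=(2, 2, 6), size=(2, 2, 6))
    mesh.element_part[: mesh.n_elements // 2] = GAP
    mats = make_mats(mesh, E=100.0, nu=0.0)
    lc = LoadCase(
        fixed_nodes=nodes_on_plane(mesh, 2, 0.0),
        load_nodes=nodes_on_plane(mesh, 2, 6.0),
        force=(1.0, 2.0, -3.0),
    )
    sol = solve(assemble_stiffness(mesh, mats), lc, mesh, mats)
    result = max_von_mises_by_part(sol, mesh)
    assert set(result) == {"bone", "gap"}
    for name, code in (("bone", BONE), ("gap", GAP)):
        sel = np.flatnonzero(mesh.element_part == code)
        best = sel[np.argmax(sol.von_mises[sel])]
        assert result[name] == (pytest.approx(sol.von_mises[best]), best)


def test_uniform_stress_max_breaks_ties_at_lowest_element():
    mesh = bar_mesh(n=(2, 2, 4), size=(2, 2, 4))
    sol = fe.FieldSolution(
        displacement=np.zeros((mesh.n_nodes, 3)),
        strain=np.zeros((mesh.n_elements, 6)),
        stress=np.tile([5.0, 0, 0, 0, 0, 0], (mesh.n_elements, 1)),
        von_mises=np.full(mesh.n_elements, 5.0),
    )
    result = max_von_mises_by_part(sol, mesh)
    assert result["bone"] == (5.0, 0)
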