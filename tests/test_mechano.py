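"""Strain invariants, healing-zone classification, zone census, IFM."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fracenv as fe
from fracenv.mechano import (
    OSSIFICATION_ZONES,
    ZONE_ENDOCHONDRAL,
    ZONE_EXCESS,
    ZONE_INTRAMEMBRANOUS,
    ZONE_RESORPTION,
    HealingZoneRule,
    StrainInvariants,
    Zone,
)
from fracenv.meshmat import TetMesh
from fracenv.volume import BONE, GAP


def random_symmetric(rng, n):
    a = rng.normal(size=(n, 3, 3))
    return 0.5 * (a + a.transpose(0, 2, 1))


def random_rotations(rng, n):
    q, _ = np.linalg.qr(rng.normal(size=(n, 3, 3)))
    det = np.linalg.det(q)
    q[det < 0, :, 0] *= -1
    return q


def test_volumetric_strain_closed_forms():
    assert fe.volumetric_strain(np.diag([0.01, -0.005, -0.005])) == (
        pytest.approx(0.0, abs=1e-15)
    )
    assert fe.volumetric_strain(np.diag([0.01, 0.01, 0.01])) == (
        pytest.approx(0.03)
    )


def test_octahedral_shear_strain_closed_forms():
    assert fe.octahedral_shear_strain(np.diag([0.02, 0.02, 0.02])) == (
        pytest.approx(0.0, abs=1e-12)
    )
    expected = (2.0 / 3.0) * np.sqrt(2e-4)
    assert fe.octahedral_shear_strain(np.diag([0.01, 0.0, 0.0])) == (
        pytest.approx(expected)
    )


def test_octahedral_dual_formula_on_random_tensors(rng):
    eps = random_symmetric(rng, 1000) * 0.01
    gamma = fe.octahedral_shear_strain(eps)
    tr = np.trace(eps, axis1=1, axis2=2)
    dev = eps - tr[:, None, None] / 3.0 * np.eye(3)
    j2 = 0.5 * np.einsum("nij,nij->n", dev, dev)
    gamma_j2 = 2.0 * np.sqrt(2.0 * j2 / 3.0)
    assert np.abs(gamma - gamma_j2).max() <= 1e-10
    assert np.all(gamma >= 0)


def test_hydrostatic_pressure_sign_and_linearity():
    assert fe.hydrostatic_pressure(np.diag([-3.0, -3.0, -3.0])) == (
        pytest.approx(3.0)
    )  # compression positive
    shear = np.zeros((3, 3))
    shear[0, 1] = shear[1, 0] = 7.0
    assert fe.hydrostatic_pressure(shear) == pytest.approx(0.0, abs=1e-15)
    s = np.diag([1.0, 2.0, 3.0])
    assert fe.hydrostatic_pressure(2.5 * s) == pytest.approx(
        2.5 * fe.hydrostatic_pressure(s)
    )


def test_invariants_are_rotation_invariant(rng):
    eps = random_symmetric(rng, 200) * 0.02
    q = random_rotations(rng, 200)
    rotated = np.einsum("nab,nbc,ndc->nad", q, eps, q)
    assert np.abs(
        fe.volumetric_strain(rotated) - fe.volumetric_strain(eps)
    ).max() <= 1e-10
    assert np.abs(
        fe.octahedral_shear_strain(rotated) - fe.octahedral_shear_strain(eps)
    ).max() <= 1e-10
    assert np.abs(
        fe.von_mises(rotated) - fe.von_mises(eps)
    ).max() <= 1e-10 * max(1.0, np.abs(fe.von_mises(eps)).max())


def _inv(gamma, p):
    n = np.size(gamma)
    return StrainInvariants(
        eps_vol=np.zeros(n),
        gamma_oct=np.atleast_1d(np.asarray(gamma, dtype=float)),
        p_hydro=np.atleast_1d(np.asarray(p, dtype=float)),
    )


def test_default_rule_classification_table():
    rule = fe.default_rule()
    assert fe.classify_elements(_inv(0.02, 0.10), rule)[0] == (
        ZONE_INTRAMEMBRANOUS
    )
    for p in (-1.0, 0.0, 1.0):  # too much distortion regardless of pressure
        assert fe.classify_elements(_inv(0.40, p), rule)[0] == ZONE_EXCESS
    assert fe.classify_elements(_inv(0.10, 0.5), rule)[0] == ZONE_ENDOCHONDRAL
    # moderate strain without compressive pressure: excessive stimulus
    assert fe.classify_elements(_inv(0.10, 0.0), rule)[0] == ZONE_EXCESS


def test_low_stimulus_band_is_optional():
    banded = fe.default_rule(include_resorption_band=True)
    plain = fe.default_rule(include_resorption_band=False)
    assert fe.classify_elements(_inv(0.0, 0.0), banded)[0] == ZONE_RESORPTION
    assert fe.classify_elements(_inv(0.0, 0.0), plain)[0] == (
        ZONE_INTRAMEMBRANOUS
    )


def test_non_covering_rule_rejected():
    with pytest.raises(ValueError, match="cover"):
        HealingZoneRule([Zone("only", gamma_max=0.1)])


def test_invariants_scale_linearly_with_load(rng):
    """Linear elasticity: scaling the strain/stress state scales all
    stimuli by the same factor."""
    eps = random_symmetric(rng, 100) * 0.02
    sig = random_symmetric(rng, 100) * 5.0
    for a in (0.5, 3.0):
        assert np.allclose(
            fe.octahedral_shear_strain(a * eps),
            a * fe.octahedral_shear_strain(eps),
        )
        assert np.allclose(
            fe.volumetric_strain(a * eps), a * fe.volumetric_strain(eps)
        )
        assert np.allclose(
            fe.hydrostatic_pressure(a * sig),
            a * fe.hydrostatic_pressure(sig),
        )


def test_pure_distortion_ray_progresses_through_zones_monotonically(rng):
    """Along a pressure-free loading ray, growing stimulus can only move an
    element low-stimulus -> bony formation -> excess, never backwards.
    (With pressure-gated zones the ordering is not total: a fibrous element
    can re-enter the endochondral box when compression crosses its
    threshold, so only the distortion ray is asserted.)"""
    rule = fe.default_rule(include_resorption_band=True)
    order = {name: i for i, name in enumerate(rule.zone_names)}
    gamma = rng.uniform(1e-4, 0.04, size=200)
    before = fe.classify_elements(_inv(gamma, np.zeros_like(gamma)), rule)
    for factor in (2.0, 10.0, 100.0):
        after = fe.classify_elements(
            _inv(factor * gamma, np.zeros_like(gamma)), rule
        )
        assert all(order[b] <= order[a] for b, a in zip(before, after))


@given(
    v=st.lists(st.floats(-0.1, 0.1), min_size=6, max_size=6),
    a=st.floats(0.0, 50.0),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_octahedral_strain_is_nonnegative_and_homogeneous(v, a):
    eps = np.array(v)
    g = fe.octahedral_shear_strain(eps)
    assert g >= 0.0
    assert fe.octahedral_shear_strain(a * eps) == pytest.approx(
        a * g, rel=1e-9, abs=1e-15
    )


def test_zone_fractions_reporting_arithmetic():
    rule = fe.default_rule()
    labels = np.array(
        [ZONE_EXCESS] * 20_773
        + [ZONE_INTRAMEMBRANOUS] * (74_977 - 20_773),
        dtype=object,
    )
    summary = fe.zone_fractions(labels, rule)
    assert summary["total"] == 74_977
    assert summary["counts"][ZONE_EXCESS] == 20_773
    assert summary["fractions"][ZONE_EXCESS] == pytest.approx(
        0.27706, abs=1e-5
    )
    assert summary["headline_percent"][ZONE_EXCESS] == 28
    assert sum(summary["fractions"].values()) == pytest.approx(1.0,
                                                               abs=1e-12)


def test_single_zone_gets_all_elements():
    rule = fe.default_rule()
    labels = np.array([ZONE_INTRAMEMBRANOUS] * 10, dtype=object)
    summary = fe.zone_fractions(labels, rule)
    assert summary["fractions"][ZONE_INTRAMEMBRANOUS] == 1.0
    assert summary["headline_percent"][ZONE_INTRAMEMBRANOUS] == 100


def _gap_sandwich_mesh():
    """Bone slabs at z in [0,2] and [3,5] around a gap slab in [2,3]."""
    labels = np.full((3, 3, 5), BONE, dtype=int)
    labels[:, :, 2] = GAP
    return fe.voxels_to_tets(labels, (1.0, 1.0, 1.0))


def _solution_with_displacement(mesh, u):
    m = mesh.n_elements
    return fe.FieldSolution(
        displacement=u,
        strain=np.zeros((m, 6)),
        stress=np.zeros((m, 6)),
        von_mises=np.zeros(m),
    )


@pytest.mark.parametrize(
    "shift,expected_axial,expected_shear",
    [
        ((0.0, 0.0, -0.5), 0.5, 0.0),
        ((0.2, 0.0, 0.0), 0.0, 0.2),
        ((0.0, 0.0, 0.0), 0.0, 0.0),
    ],
)
def test_interfragmentary_movement_for_rigid_fragment_motion(
    shift, expected_axial, expected_shear
):
    mesh = _gap_sandwich_mesh()
    u = np.zeros((mesh.n_nodes, 3))
    u[mesh.nodes[:, 2] > 2.5] = shift  # move the proximal fragment rigidly
    sol = _solution_with_displacement(mesh, u)
    axial, shear = fe.interfragmentary_movement(sol, mesh, (0, 0, 1.0))
    assert axial == pytest.approx(expected_axial, abs=1e-12)
    assert shear == pytest.approx(expected_shear, abs=1e-12)


def test_ifm_requires_identifiable_interfaces():
    labels = np.full((2, 2, 2), BONE, dtype=int)
    mesh = fe.voxels_to_tets(labels, (1, 1, 1))
    sol = _solution_with_displacement(mesh, np.zeros((mesh.n_nodes, 3)))
    with pytest.raises(ValueError, match="missing parts"):
        fe.interfragmentary_movement(sol, mesh, (0, 0, 1.0))


def test_ossification_zones_are_the_two_formation_zones():
    assert set(OSSIFICATION_ZONES) == {ZONE_INTRAMEMBRANOUS,
                                       ZONE_ENDOCHONDRAL}
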