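"""Label volume -> conforming tetrahedral mesh with per-element materials.

Each foreground voxel is split into six tetrahedra (Kuhn/Freudenthal
subdivision about the voxel's main diagonal).  Using the same corner ordering
for every voxel makes face diagonals agree across voxel boundaries, so the
mesh is globally conforming, and the subdivision is volume-exact.  TET10
elements promote every edge to a midside node at the straight-edge midpoint
(quadratic interpolation over affine, straight-sided elements).

Bone elements receive a heterogeneous Young's modulus through the classic
QCT chain: equivalent mineral density (from calibration) -> ash density
(affine law) -> cortical power law or trabecular affine law, discriminated by
an ash-density threshold.  Nail/screws and fracture gap are homogeneous
material cards.  Note the cortical and trabecular laws do not agree at the
class threshold; the jump is a documented property of the published
relations, not hidden by blending.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import BONE, GAP, IMPLANT, ImageVolume

# tissue class codes in MaterialField
CLASS_CORTICAL = 0
CLASS_TRABECULAR = 1
CLASS_IMPLANT = 2
CLASS_GAP = 3
CLASS_NAMES = {
    CLASS_CORTICAL: "cortical",
    CLASS_TRABECULAR: "trabecular",
    CLASS_IMPLANT: "implant",
    CLASS_GAP: "gap",
}

# Kuhn subdivision: cube corners indexed by bit pattern (x, y, z); the six
# tets are the chains 0 -> a -> b -> 7 along cube edges (shared diagonal 0-7)
_CUBE_CORNERS = np.array(
    [(i, j, k) for k in (0, 1) for j in (0, 1) for i in (0, 1)]
)  # corner c = (c & 1, (c >> 1) & 1, (c >> 2) & 1) -> index i + 2j + 4k
_KUHN_PATHS = (
    (0, 1, 3, 7),
    (0, 1, 5, 7),
    (0, 2, 3, 7),
    (0, 2, 6, 7),
    (0, 4, 5, 7),
    (0, 4, 6, 7),
)


def _corner_offset(c: int) -> tuple[int, int, int]:
    return (c & 1, (c >> 1) & 1, (c >> 2) & 1)


@dataclass
class TetMesh:
    """Tetrahedral mesh in mm; TET4 (order 1) or TET10 (order 2).

    TET10 connectivity follows the VTK quadratic-tet convention: corners
    0..3, then midside nodes on edges (0,1), (1,2), (0,2), (0,3), (1,3),
    (2,3).
    """

    nodes: np.ndarray  # (n_nodes, 3) float
    elements: np.ndarray  # (n_elem, 4) or (n_elem, 10) int
    element_part: np.ndarray  # (n_elem,) int label codes
    order: int = 1

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def corner_coords(self) -> np.ndarray:
        """(n_elem, 4, 3) corner coordinates."""
        return self.nodes[self.elements[:, :4]]

    def volumes(self) -> np.ndarray:
        """Signed tet volumes (positive for consistent orientation)."""
        x = self.corner_coords()
        e = x[:, 1:] - x[:, :1]
        return np.linalg.det(e) / 6.0

    def centroids(self) -> np.ndarray:
        return self.corner_coords().mean(axis=1)


_EDGES10 = ((0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3))


def voxels_to_tets(
    labels: np.ndarray,
    spacing,
    order: int = 1,
    origin=(0.0, 0.0, 0.0),
    include_labels=(BONE, GAP, IMPLANT),
) -> TetMesh:
    """Mesh every voxel whose label is in ``include_labels``.

    Six tets per voxel, element_part inherits the voxel label; order 2 adds
    globally deduplicated midside nodes at edge midpoints.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    labels = np.asarray(labels)
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    fg = np.isin(labels, list(include_labels))
    if not fg.any():
        raise ValueError("no foreground voxels to mesh")

    nx, ny, nz = labels.shape
    vox = np.argwhere(fg)  # (n_vox, 3)
    part = labels[fg]

    # global corner-node ids on the (nx+1, ny+1, nz+1) grid
    def grid_id(ijk):
        return (ijk[:, 0] * (ny + 1) + ijk[:, 1]) * (nz + 1) + ijk[:, 2]

    corner_ids = np.empty((len(vox), 8), dtype=np.int64)
    for c in range(8):
        off = np.array(_corner_offset(c))
        corner_ids[:, c] = grid_id(vox + off)

    tets = np.concatenate(
        [corner_ids[:, list(path)] for path in _KUHN_PATHS], axis=0
    )
    # interleave so the 6 tets of a voxel are contiguous
    n_vox = len(vox)
    order_idx = np.arange(6 * n_vox).reshape(6, n_vox).T.ravel()
    tets = tets[order_idx]
    element_part = np.repeat(part, 6)

    used, inv = np.unique(tets, return_inverse=True)
    elements = inv.reshape(tets.shape).astype(np.int64)
    gi, gj = divmod(used, (nz + 1))
    gii, gjj = divmod(gi, (ny + 1))
    nodes = np.stack([gii, gjj, gj], axis=1).astype(float) * spacing + origin

    # fix orientation: make all volumes positive by swapping nodes 1, 2 where
    # needed (the six Kuhn types each have a fixed sign)
    mesh = TetMesh(nodes, elements, element_part, order=1)
    vols = mesh.volumes()
    neg = vols < 0
    if neg.any():
        elements[neg] = elements[neg][:, [0, 2, 1, 3]]
        mesh = TetMesh(nodes, elements, element_part, order=1)
        vols = mesh.volumes()
    if not (vols > 0).all():
        bad = int(np.flatnonzero(vols <= 0)[0])
        raise ValueError(f"degenerate element {bad} with volume {vols[bad]}")

    if order == 1:
        return mesh

    # promote to TET10: unique midside node per global edge
    corner_pairs = elements[:, _EDGES10]  # (n_elem, 6, 2)
    lo = corner_pairs.min(axis=2)
    hi = corner_pairs.max(axis=2)
    key = lo.astype(np.int64) * mesh.n_nodes + hi
    uniq, inv = np.unique(key, return_inverse=True)
    mid_ids = mesh.n_nodes + inv.reshape(lo.shape)
    ulo, uhi = divmod(uniq, mesh.n_nodes)
    mid_nodes = 0.5 * (nodes[ulo] + nodes[uhi])
    return TetMesh(
        nodes=np.vstack([nodes, mid_nodes]),
        elements=np.hstack([elements, mid_ids]),
        element_part=element_part,
        order=2,
    )


# --- density-elasticity mapping ------------------------------------------

ASH_SLOPE = 1.22  # ash density per equivalent mineral density
ASH_INTERCEPT = 0.0523  # g/cm^3
CORT_COEFF = 10_200.0  # MPa at ash density 1 g/cm^3
CORT_EXP = 2.01
TRAB_SLOPE = 5_307.0  # MPa per (g/cm^3)
TRAB_INTERCEPT = 469.0  # MPa


def ash_density(rho_eqm):
    """Ash density (g/cm^3) from equivalent mineral density (g/cm^3)."""
    rho_eqm = np.asarray(rho_eqm, dtype=float)
    if np.any(rho_eqm < 0):
        raise ValueError("equivalent mineral density must be >= 0 "
                         "(clamp upstream)")
    out = ASH_SLOPE * rho_eqm + ASH_INTERCEPT
    return out if out.ndim else float(out)


def modulus_cortical(rho_ash):
    """Cortical Young's modulus (MPa), power law in ash density."""
    rho_ash = np.asarray(rho_ash, dtype=float)
    if np.any(rho_ash < 0):
        raise ValueError("ash density must be >= 0")
    out = CORT_COEFF * rho_ash**CORT_EXP
    return out if out.ndim else float(out)


def modulus_trabecular(rho_ash):
    """Trabecular Young's modulus (MPa), affine in ash density."""
    rho_ash = np.asarray(rho_ash, dtype=float)
    if np.any(rho_ash < 0):
        raise ValueError("ash density must be >= 0")
    out = TRAB_SLOPE * rho_ash + TRAB_INTERCEPT
    return out if out.ndim else float(out)


@dataclass
class MaterialCard:
    """Homogeneous constants and classification settings."""

    implant_modulus: float = 108_000.0  # MPa (Ti alloy nail and screws)
    implant_poisson: float = 0.37
    gap_modulus: float = 3.0  # MPa (initial connective tissue)
    gap_poisson: float = 0.4
    bone_poisson: float = 0.30
    cortical_ash_threshold: float = 0.6  # g/cm^3; >= -> cortical law
    yield_strength: float = 860.0  # MPa, Ti alloy minimum
    tensile_strength: float = 930.0  # MPa


@dataclass
class MaterialField:
    """Per-element isotropic elastic constants."""

    young_modulus: np.ndarray  # MPa
    poisson_ratio: np.ndarray
    ash_density: np.ndarray  # g/cm^3, NaN for non-bone elements
    tissue_class: np.ndarray  # CLASS_* codes

    def __post_init__(self) -> None:
        if np.any(self.young_modulus <= 0):
            raise ValueError("Young's modulus must be positive")
        if np.any((self.poisson_ratio < 0) | (self.poisson_ratio >= 0.5)):
            raise ValueError("Poisson ratio must be in [0, 0.5)")


def assign_materials(
    mesh: TetMesh,
    density_volume: ImageVolume,
    card: MaterialCard | None = None,
) -> MaterialField:
    """Per-element material assignment.

    Implant and gap elements get their homogeneous card values.  Bone
    elements sample the calibrated density volume at the voxel containing the
    element centroid, map it to ash density, and take the cortical power law
    when the ash density reaches the class threshold, the trabecular affine
    law otherwise.
    """
    card = card or MaterialCard()
    n = mesh.n_elements
    E = np.empty(n)
    nu = np.empty(n)
    ash = np.full(n, np.nan)
    tclass = np.empty(n, dtype=np.int8)

    cent = mesh.centroids()
    idx = np.floor(
        (cent - np.asarray(density_volume.origin))
        / np.asarray(density_volume.spacing)
    ).astype(int)
    shape = np.asarray(density_volume.shape)
    if np.any(idx < 0) or np.any(idx >= shape):
        bad = int(np.flatnonzero((idx < 0).any(1) | (idx >= shape).any(1))[0])
        raise ValueError(
            f"element {bad} centroid {cent[bad]} lies outside the density volume"
        )

    part = mesh.element_part
    imp = part == IMPLANT
    gapm = part == GAP
    bone = part == BONE
    E[imp] = card.implant_modulus
    nu[imp] = card.implant_poisson
    tclass[imp] = CLASS_IMPLANT
    E[gapm] = card.gap_modulus
    nu[gapm] = card.gap_poisson
    tclass[gapm] = CLASS_GAP

    if bone.any():
        rho_eqm = np.maximum(
            density_volume.data[idx[bone, 0], idx[bone, 1], idx[bone, 2]], 0.0
        )
        rho_ash = ash_density(rho_eqm)
        cort = rho_ash >= card.cortical_ash_threshold
        Eb = np.where(
            cort, CORT_COEFF * rho_ash**CORT_EXP, TRAB_SLOPE * rho_ash
            + TRAB_INTERCEPT
        )
        E[bone] = Eb
        nu[bone] = card.bone_poisson
        ash[bone] = rho_ash
        tclass[bone] = np.where(cort, CLASS_CORTICAL, CLASS_TRABECULAR)

    unknown = ~(imp | gapm | bone)
    if unknown.any():
        raise ValueError(
            f"elements with unsupported part labels: {np.unique(part[unknown])}"
        )
    return MaterialField(E, nu, ash, tclass)
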