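"""Synthetic calibrated-CT phantom of a nailed, fractured tibia.

The phantom is an idealized axis-aligned tibia: a cortical shell around a
trabecular ring and a medullary canal, bridged by an intramedullary nail with
transverse locking screws, interrupted by a soft fracture gap of configurable
width and obliquity.  Six calibration rods of known equivalent mineral density
(a bone-density calibration ladder) run parallel to the bone outside the leg.
Bone and rod voxels follow a linear HU-density law with additive Gaussian
noise; implant and gap voxels are noise-free constants.

The generator returns both the HU volume and a full ground truth (labels,
per-voxel density, the HU law), so every downstream stage of the pipeline has
a known-answer input.

Key geometric choice: the nail diameter is strictly smaller than the canal so
that at the default voxel spacing at least one voxel of (unlabeled) marrow
separates nail and bone everywhere.  The nail therefore connects to the bone
only through its locking screws, which is what gives the construct a
clinically plausible axial compliance under load.  The nail also ends a few mm
short of the volume faces so that axial boundary conditions act on bone only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .volume import (
    BACKGROUND,
    BONE,
    GAP,
    IMPLANT,
    ImageVolume,
    rod_label,
)


class PhantomGeometryError(ValueError):
    """Raised when the requested geometry does not fit the volume."""


@dataclass
class PhantomSpec:
    """Parameters of the synthetic phantom.

    Lengths in mm, densities in g/cm^3 (hydroxyapatite-equivalent), HU values
    on the CT scale.  ``screw_spec`` lists transverse locking screws as
    (axial position mm, diameter mm); screws run along x through the whole
    bone width.  ``rod_densities`` must be six strictly increasing values.
    """

    volume_shape: tuple[int, int, int] = (40, 32, 32)
    voxel_spacing: tuple[float, float, float] = (1.25, 1.25, 2.5)
    cortical_outer_radius: float = 11.5
    cortical_inner_radius: float = 8.5
    canal_radius: float = 6.5
    nail_diameter: float = 9.0
    screw_spec: tuple[tuple[float, float], ...] = (
        (15.0, 4.0),
        (25.0, 4.0),
        (60.0, 4.0),
        (70.0, 4.0),
    )
    gap_width: float = 3.0
    gap_obliquity: float = 0.0  # degrees from transverse
    rod_densities: tuple[float, ...] = (0.0, 0.1, 0.2, 0.4, 0.6, 0.8)
    hu_slope: float = 1000.0  # HU per (g/cm^3)
    hu_intercept: float = 0.0  # HU
    noise_sd: float = 5.0  # HU
    implant_hu: float = 3000.0
    gap_hu: float = 20.0
    seed: int = 0
    # layout and tissue knobs (auto-derived when None)
    cortical_density: float = 0.9  # g/cm^3 equivalent mineral density
    trabecular_density: float = 0.25
    rod_radius: float = 2.5
    bone_center: tuple[float, float] | None = None  # (x, y) mm
    rod_centers: tuple[tuple[float, float], ...] | None = None
    gap_center_z: float | None = None  # mm; default: volume mid-height
    nail_end_margin: float = 5.0  # mm the nail stops short of each z face

    def __post_init__(self) -> None:
        self.volume_shape = tuple(int(n) for n in self.volume_shape)
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        self.rod_densities = tuple(float(d) for d in self.rod_densities)
        self.screw_spec = tuple((float(z), float(d)) for z, d in self.screw_spec)
        self.validate()

    def validate(self) -> None:
        if len(self.volume_shape) != 3 or any(n < 2 for n in self.volume_shape):
            raise PhantomGeometryError(f"bad volume_shape {self.volume_shape}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise PhantomGeometryError(f"bad voxel_spacing {self.voxel_spacing}")
        if not (0 < self.canal_radius < self.cortical_inner_radius
                < self.cortical_outer_radius):
            raise PhantomGeometryError(
                "need canal_radius < cortical_inner_radius < cortical_outer_radius, "
                f"got {self.canal_radius}, {self.cortical_inner_radius}, "
                f"{self.cortical_outer_radius}"
            )
        if self.nail_diameter / 2 > self.canal_radius:
            raise PhantomGeometryError(
                f"nail (diameter {self.nail_diameter} mm) does not fit the canal "
                f"(radius {self.canal_radius} mm)"
            )
        if len(self.rod_densities) != 6:
            raise PhantomGeometryError("exactly six rod densities are required")
        if not np.all(np.diff(self.rod_densities) > 0):
            raise PhantomGeometryError("rod densities must be strictly increasing")
        if self.noise_sd < 0:
            raise PhantomGeometryError("noise_sd must be >= 0")
        if self.gap_width <= 0:
            raise PhantomGeometryError("gap_width must be > 0")

    # --- derived layout -------------------------------------------------
    def extent(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.volume_shape, self.voxel_spacing))

    def bone_xy(self) -> tuple[float, float]:
        if self.bone_center is not None:
            return tuple(float(c) for c in self.bone_center)
        lx, ly, _ = self.extent()
        return (lx / 2.0, 0.625 * ly)

    def rod_xy(self) -> tuple[tuple[float, float], ...]:
        if self.rod_centers is not None:
            return tuple((float(x), float(y)) for x, y in self.rod_centers)
        lx, ly, _ = self.extent()
        margin = 1.5
        pitch = (lx - 2 * margin - 2 * self.rod_radius) / 5.0
        y = 0.15 * ly
        return tuple(
            (margin + self.rod_radius + i * pitch, y) for i in range(6)
        )

    def gap_z(self) -> float:
        if self.gap_center_z is not None:
            return float(self.gap_center_z)
        return self.extent()[2] / 2.0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Known-answer companion of a generated phantom."""

    labels: np.ndarray  # integer label codes, same grid as the volume
    hu_law: tuple[float, float]  # (slope HU/(g/cm^3), intercept HU)
    density: np.ndarray  # per-voxel true equivalent mineral density, g/cm^3
    seed: int
    spec: PhantomSpec


def _check_circle_inside(cx, cy, r, lx, ly, what):
    if cx - r < 0 or cy - r < 0 or cx + r > lx or cy + r > ly:
        raise PhantomGeometryError(
            f"{what} (center ({cx:.1f}, {cy:.1f}) mm, radius {r:.1f} mm) "
            f"does not fit the {lx:.1f} x {ly:.1f} mm cross-section"
        )


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, GroundTruth]:
    """Rasterize the phantom onto the voxel grid.

    A voxel belongs to a region iff its center point does; overlaps resolve
    with priority implant > gap > bone > rod > background.  Deterministic for
    a fixed ``spec.seed``.
    """
    spec.validate()
    lx, ly, lz = spec.extent()
    bcx, bcy = spec.bone_xy()
    rods = spec.rod_xy()
    _check_circle_inside(bcx, bcy, spec.cortical_outer_radius, lx, ly, "bone")
    for k, (rx, ry) in enumerate(rods, start=1):
        _check_circle_inside(rx, ry, spec.rod_radius, lx, ly, f"rod {k}")
        d = np.hypot(rx - bcx, ry - bcy)
        if d < spec.cortical_outer_radius + spec.rod_radius:
            raise PhantomGeometryError(f"rod {k} overlaps the bone")
    for zpos, diam in spec.screw_spec:
        if not (0 <= zpos - diam / 2 and zpos + diam / 2 <= lz):
            raise PhantomGeometryError(
                f"screw at z={zpos} mm (diameter {diam} mm) exceeds the "
                f"{lz:.1f} mm volume height"
            )

    dummy = ImageVolume(
        np.zeros(spec.volume_shape), spec.voxel_spacing, (0.0, 0.0, 0.0)
    )
    x, y, z = dummy.voxel_centers()
    shape = spec.volume_shape

    r2 = (x - bcx) ** 2 + (y - bcy) ** 2
    cortical = (r2 <= spec.cortical_outer_radius**2) & (
        r2 > spec.cortical_inner_radius**2
    )
    trabecular = (r2 <= spec.cortical_inner_radius**2) & (
        r2 > spec.canal_radius**2
    )
    bone_region = np.broadcast_to(cortical | trabecular, shape)
    cortical = np.broadcast_to(cortical, shape)

    # fracture gap: slab of width gap_width about a plane through gap_z whose
    # normal is tilted gap_obliquity degrees from the bone axis (about y)
    theta = np.deg2rad(spec.gap_obliquity)
    n = np.array([-np.sin(theta), 0.0, np.cos(theta)])
    dist = n[0] * (x - bcx) + n[2] * (z - spec.gap_z())
    slab = np.broadcast_to(np.abs(dist) <= spec.gap_width / 2.0, shape)
    in_bone_footprint = np.broadcast_to(
        (r2 <= spec.cortical_outer_radius**2) & (r2 > spec.canal_radius**2),
        shape,
    )
    gap_region = slab & in_bone_footprint

    nail = np.broadcast_to(r2 <= (spec.nail_diameter / 2.0) ** 2, shape) & (
        np.broadcast_to(
            (z >= spec.nail_end_margin) & (z <= lz - spec.nail_end_margin), shape
        )
    )
    implant = nail.copy()
    for zpos, diam in spec.screw_spec:
        screw = ((y - bcy) ** 2 + (z - zpos) ** 2 <= (diam / 2.0) ** 2) & (
            np.abs(x - bcx) <= spec.cortical_outer_radius
        )
        implant |= np.broadcast_to(screw, shape)

    labels = np.full(shape, BACKGROUND, dtype=np.int16)
    density_design = np.zeros(shape)
    for k, ((rx, ry), rho) in enumerate(zip(rods, spec.rod_densities), start=1):
        rod = np.broadcast_to((x - rx) ** 2 + (y - ry) ** 2 <= spec.rod_radius**2,
                              shape)
        labels[rod] = rod_label(k)
        density_design[rod] = rho
    labels[bone_region] = BONE
    density_design[bone_region & ~cortical] = spec.trabecular_density
    density_design[cortical] = spec.cortical_density
    labels[gap_region] = GAP
    density_design[gap_region] = 0.0
    labels[implant] = IMPLANT
    density_design[implant] = 0.0

    clean_hu = spec.hu_slope * density_design + spec.hu_intercept
    clean_hu = np.where(labels == IMPLANT, spec.implant_hu, clean_hu)
    clean_hu = np.where(labels == GAP, spec.gap_hu, clean_hu)

    rng = np.random.default_rng(spec.seed)
    hu = clean_hu.copy()
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=shape)
        noisy = (labels != IMPLANT) & (labels != GAP)
        hu[noisy] += noise[noisy]

    # ground-truth density: the noise-free HU mapped back through the linear
    # law (clamped at zero), so calibration round-trips are exact by design
    if spec.hu_slope == 0:
        raise PhantomGeometryError("hu_slope must be nonzero")
    density_true = np.maximum((clean_hu - spec.hu_intercept) / spec.hu_slope, 0.0)

    vol = ImageVolume(hu, spec.voxel_spacing, (0.0, 0.0, 0.0))
    gt = GroundTruth(
        labels=labels,
        hu_law=(spec.hu_slope, spec.hu_intercept),
        density=density_true,
        seed=spec.seed,
        spec=spec,
    )
    return vol, gt


def gap_plane_normal(spec: PhantomSpec) -> np.ndarray:
    """Unit normal of the fracture plane (points proximally, +z-ish)."""
    theta = np.deg2rad(spec.gap_obliquity)
    return np.array([-np.sin(theta), 0.0, np.cos(theta)])
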