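"""Mask-generation chain for the calibrated CT volume.

The chain mirrors a semi-automated clinical segmentation sequence:
density-adaptive thresholding into implant and bone masks (the bone threshold
is stated in calibrated density units and converted per scan through the
calibration model), a morphological close with an isotropic ball, Gaussian
mask smoothing with per-axis sigmas in mm, island removal, cavity fill, and a
priority-ordered label resolution.  The fracture-gap mask is derived
deterministically: the morphological close of the bone mask (with a radius
spanning the gap) minus bone minus implant, trimmed to the region between the
two bone fragments.

All component operations use 26-connectivity; structuring elements are
Euclidean balls in voxel units.  Every step appends a line to the mask set's
provenance log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .calibration import CalibrationModel
from .volume import BACKGROUND, BONE, GAP, IMPLANT, ImageVolume

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SegmentationParams:
    """Tunable parameters of the segmentation chain.

    ``implant_threshold`` is in HU (metal is far above any tissue);
    ``bone_threshold`` is in calibrated equivalent mineral density (g/cm^3)
    and is converted to HU through the per-scan calibration model.
    """

    implant_threshold: float = 2000.0  # HU
    bone_threshold: float = 0.15  # g/cm^3
    close_radius: int = 0  # voxels, isotropic ball
    smooth_sigma: tuple[float, float, float] = (0.4, 0.4, 0.4)  # mm per axis
    min_island_size: int = 30  # voxels
    gap_close_radius: int = 2  # voxels; must span the fracture gap
    priority_order: tuple[str, ...] = ("implant", "gap", "bone")

    def __post_init__(self) -> None:
        if not np.isfinite([self.implant_threshold, self.bone_threshold]).all():
            raise ValueError("thresholds must be finite")
        if self.close_radius < 0 or self.gap_close_radius < 0:
            raise ValueError("close radii must be >= 0")
        if any(s < 0 for s in self.smooth_sigma):
            raise ValueError("smooth_sigma must be >= 0 per axis")


@dataclass
class MaskSet:
    """Named binary masks plus a provenance log of the applied steps."""

    masks: dict[str, np.ndarray]
    provenance: list[str] = field(default_factory=list)

    def log(self, step: str) -> None:
        self.provenance.append(step)


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    return dx**2 + dy**2 + dz**2 <= r**2 + 1e-9


def threshold_masks(
    vol: ImageVolume,
    cal: CalibrationModel,
    params: SegmentationParams,
    exclude: np.ndarray | None = None,
) -> MaskSet:
    """Density-adaptive thresholding into implant / bone masks.

    implant = HU >= implant_threshold; bone = (calibrated density >=
    bone_threshold) and not implant.  ``exclude`` marks voxels that are
    known not to be anatomy (the calibration-rod region; rod labels are an
    input, as for calibration) and is removed from both masks.  The gap mask
    starts empty and is filled later by :func:`derive_gap_mask`.
    """
    implant = vol.data >= params.implant_threshold
    hu_thr = cal.hu_at_density(params.bone_threshold)
    bone = (vol.data >= hu_thr) & ~implant
    if exclude is not None:
        implant = implant & ~exclude
        bone = bone & ~exclude
    ms = MaskSet(
        {"implant": implant, "bone": bone, "gap": np.zeros_like(implant)}
    )
    ms.log(
        f"threshold: implant >= {params.implant_threshold} HU; bone >= "
        f"{params.bone_threshold} g/cm^3 (= {hu_thr:.1f} HU via calibration)"
    )
    return ms


def morph_close(mask: np.ndarray, radius_voxels: int) -> np.ndarray:
    """Morphological closing (dilate then erode) with a voxel-unit ball."""
    if radius_voxels < 0:
        raise ValueError("radius must be >= 0")
    if radius_voxels == 0:
        return mask.copy()
    r = int(radius_voxels)
    se = _ball(r)
    # pad so the closing is computed on an unbounded domain (no border
    # clipping of the dilation, no border inflation of the erosion)
    padded = np.pad(mask, r, mode="constant", constant_values=False)
    dil = ndimage.binary_dilation(padded, structure=se)
    ero = ndimage.binary_erosion(dil, structure=se, border_value=0)
    return ero[r:-r, r:-r, r:-r]


def smooth_mask(mask, sigma_mm, spacing) -> np.ndarray:
    """Gaussian-smooth the binary indicator and re-threshold at 0.5.

    Sigmas are given per axis in mm (anisotropic) and converted to voxel
    units through the spacing; zero sigma is the identity.
    """
    sigma_mm = np.asarray(sigma_mm, dtype=float)
    if np.any(sigma_mm < 0):
        raise ValueError("sigma must be >= 0")
    if np.all(sigma_mm == 0):
        return mask.copy()
    sigma_vox = sigma_mm / np.asarray(spacing, dtype=float)
    blurred = ndimage.gaussian_filter(mask.astype(float), sigma=sigma_vox)
    return blurred >= 0.5


def remove_islands(
    mask: np.ndarray,
    min_size: int | None = None,
    keep_largest: bool = False,
) -> np.ndarray:
    """Drop 26-connected components below ``min_size`` (or keep the largest)."""
    if min_size is None and not keep_largest:
        raise ValueError("give min_size or keep_largest")
    lab, n = ndimage.label(mask, structure=_STRUCT26)
    if n == 0:
        return mask.copy()
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    if keep_largest:
        keep = np.zeros(n + 1, dtype=bool)
        keep[int(np.argmax(sizes))] = True
    else:
        keep = sizes >= int(min_size)
        keep[0] = False
    return keep[lab]


def fill_cavities(mask: np.ndarray) -> np.ndarray:
    """Fill background components not 26-connected to the volume border."""
    bg_lab, n = ndimage.label(~mask, structure=_STRUCT26)
    if n == 0:
        return mask.copy()
    border = np.zeros_like(mask)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    border_labels = np.unique(bg_lab[border & ~mask])
    cavity = (bg_lab > 0) & ~np.isin(bg_lab, border_labels)
    return mask | cavity


def resolve_priority(ms: MaskSet, priority_order) -> np.ndarray:
    """Collapse possibly overlapping masks into one disjoint label volume.

    A voxel claimed by several masks goes to the highest-priority claimer.
    Unlabeled voxels enclosed by the foreground envelope are assigned
    iteratively to the highest-priority 26-adjacent mask ("fill gaps").
    """
    codes = {"implant": IMPLANT, "gap": GAP, "bone": BONE}
    order = list(priority_order)
    for name in order:
        if name not in codes:
            raise ValueError(f"unknown label {name!r} in priority order")
        if name not in ms.masks:
            raise ValueError(f"mask {name!r} missing from mask set")
    if len(set(order)) != len(order):
        raise ValueError("priority order contains duplicates")

    labels = np.full(ms.masks[order[0]].shape, BACKGROUND, dtype=np.int16)
    for name in reversed(order):  # lowest priority first, higher overwrites
        labels[ms.masks[name]] = codes[name]

    union = labels != BACKGROUND
    envelope = fill_cavities(union)
    pending = envelope & ~union
    while pending.any():
        changed = False
        for name in order:
            grow = (
                ndimage.binary_dilation(labels == codes[name], structure=_STRUCT26)
                & pending
            )
            if grow.any():
                labels[grow] = codes[name]
                pending &= ~grow
                changed = True
        if not changed:  # isolated enclosed pocket with no labeled neighbor
            break
    ms.log(f"resolve_priority: order {order}")
    return labels


def derive_gap_mask(ms: MaskSet, params: SegmentationParams) -> np.ndarray:
    """Deterministic fracture-gap surrogate mask.

    Two steps.  (1) Locate: seed = close(bone, gap_close_radius) - bone -
    implant, largest connected component; the ball close spans the gap only
    where bone faces it on both sides, so the seed pins down the axial band
    of the fracture.  (2) Fill within the fragment-bounding region: inside
    the seed's axial band, every non-bone, non-implant voxel whose axial
    column contains bone both below and above (i.e. lies between the two
    fragments) is gap.  Step 2 restores the gap mouth at the cortical
    surface that the morphological close cannot reach (its closing fillet).
    """
    bone = ms.masks["bone"]
    implant = ms.masks["implant"]
    closed = morph_close(bone, params.gap_close_radius)
    raw = closed & ~bone & ~implant
    if not raw.any():
        ms.log("derive_gap_mask: no gap found")
        return raw
    seed = remove_islands(raw, keep_largest=True)
    zs = np.flatnonzero(seed.any(axis=(0, 1)))
    band = np.zeros_like(seed)
    band[:, :, zs.min(): zs.max() + 1] = True
    below = np.cumsum(bone, axis=2, dtype=np.int64) > 0  # bone at <= z
    above = np.cumsum(bone[:, :, ::-1], axis=2, dtype=np.int64)[:, :, ::-1] > 0
    between = below & above
    gap = band & between & ~bone & ~implant
    ms.log(
        f"derive_gap_mask: close radius {params.gap_close_radius} seed, "
        f"axial band slices {int(zs.min())}..{int(zs.max())}, "
        "between-fragments fill"
    )
    return gap


def segment_volume(
    vol: ImageVolume,
    cal: CalibrationModel,
    params: SegmentationParams,
    exclude: np.ndarray | None = None,
) -> tuple[MaskSet, np.ndarray]:
    """Run the full chain; returns the mask set and the final label volume.

    Disjointness and full coverage of the label volume are asserted on every
    run.
    """
    ms = threshold_masks(vol, cal, params, exclude=exclude)
    for name in ("implant", "bone"):
        m = ms.masks[name]
        m = morph_close(m, params.close_radius)
        ms.log(f"{name}: morphological close, ball radius {params.close_radius}")
        m = smooth_mask(m, params.smooth_sigma, vol.spacing)
        ms.log(f"{name}: Gaussian mask smoothing, sigma {params.smooth_sigma} mm")
        m = remove_islands(m, min_size=params.min_island_size)
        ms.log(f"{name}: island removal, min size {params.min_island_size}")
        m = fill_cavities(m)
        ms.log(f"{name}: cavity fill")
        ms.masks[name] = m
    ms.masks["gap"] = derive_gap_mask(ms, params)
    labels = resolve_priority(ms, params.priority_order)

    # invariants: disjoint by construction; coverage = every mask voxel labeled
    union = np.zeros(labels.shape, dtype=bool)
    for m in ms.masks.values():
        union |= m
    assert not (union & (labels == BACKGROUND)).any(), "coverage violated"
    return ms, labels


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks (1.0 for two empty masks)."""
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / float(denom)
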