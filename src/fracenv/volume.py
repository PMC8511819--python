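"""Image-volume container and file IO.

Arrays are indexed ``[i, j, k]`` with physical coordinates
``x = origin + (index + 0.5) * spacing`` along (x, y, z); all lengths in mm,
intensities in Hounsfield units (HU) unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

# Integer label codes shared by the phantom ground truth and the segmentation
# output.  Rod k (1-based) is ROD_BASE + k.
BACKGROUND = 0
BONE = 1
GAP = 2
IMPLANT = 3
ROD_BASE = 10

LABEL_NAMES = {
    BACKGROUND: "background",
    BONE: "bone",
    GAP: "gap",
    IMPLANT: "implant",
    **{ROD_BASE + k: f"rod_{k}" for k in range(1, 7)},
}


def rod_label(k: int) -> int:
    """Label code of calibration rod ``k`` (1-based)."""
    if not 1 <= k <= 6:
        raise ValueError(f"rod index must be in 1..6, got {k}")
    return ROD_BASE + k


@dataclass
class ImageVolume:
    """A 3-D scalar grid with voxel spacing and origin (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("ImageVolume data must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("ImageVolume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Open (broadcastable) grids of voxel-center coordinates in mm."""
        axes = []
        for n, sp, o in zip(self.data.shape, self.spacing, self.origin):
            axes.append(o + (np.arange(n) + 0.5) * sp)
        x, y, z = axes
        return x[:, None, None], y[None, :, None], z[None, None, :]

    def physical_extent(self) -> tuple[float, float, float]:
        """Edge lengths of the volume in mm."""
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing))


_FORMATS = {
    "nifti": (".nii", ".nii.gz"),
    "metaimage": (".mha", ".mhd"),
}


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    for fmt, exts in _FORMATS.items():
        if any(name.endswith(e) for e in exts):
            return fmt
    raise ValueError(
        f"cannot infer volume format from {path.name!r}; "
        "expected .nii/.nii.gz (NIfTI) or .mha/.mhd (MetaImage)"
    )


def write_volume(vol: ImageVolume, path, format: str | None = None) -> Path:
    """Write a volume to NIfTI or MetaImage.

    Round-trips through :func:`read_volume` reproduce data, spacing and origin
    bit-exactly (float64 grids are stored as float64).
    """
    path = Path(path)
    fmt = format.lower() if format else _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown volume format {format!r}")
    if not any(path.name.lower().endswith(e) for e in _FORMATS[fmt]):
        raise ValueError(f"path {path.name!r} does not match format {fmt!r}")
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.T))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))
    return path


def read_volume(path) -> ImageVolume:
    """Read a NIfTI or MetaImage volume written by :func:`write_volume`."""
    path = Path(path)
    _infer_format(path)  # raises on unknown extension
    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img).T
    return ImageVolume(
        data=data,
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
    )
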