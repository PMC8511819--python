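"""QCT density calibration: HU -> equivalent mineral density.

The six rods of the calibration ladder have known hydroxyapatite-equivalent
densities.  Per-rod HU statistics are summarized and an ordinary
least-squares line of density on the rod *median* HU gives the per-scan
calibration.  The median is used as the robust central value because rim
voxels of a rod suffer partial-volume averaging; the mean is reported
alongside.  Sample (n-1) standard deviations throughout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .volume import ImageVolume, rod_label, LABEL_NAMES

logger = logging.getLogger(__name__)


@dataclass
class CalibrationModel:
    """Linear map from HU to equivalent mineral density (g/cm^3)."""

    slope: float  # (g/cm^3) per HU
    intercept: float  # g/cm^3
    r_squared: float
    n_rods: int

    def __post_init__(self) -> None:
        if self.n_rods < 2:
            raise ValueError("calibration needs at least two rods")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared {self.r_squared} outside [0, 1]")

    def density(self, hu):
        """Predicted equivalent mineral density, clamped below at 0."""
        return np.maximum(self.slope * np.asarray(hu, dtype=float)
                          + self.intercept, 0.0)

    def hu_at_density(self, rho: float) -> float:
        """HU value whose calibrated density equals ``rho`` (inverse map)."""
        if self.slope == 0:
            raise ValueError("degenerate calibration: zero slope")
        return (rho - self.intercept) / self.slope

    def to_dict(self) -> dict:
        return asdict(self)


def extract_rod_stats(
    vol: ImageVolume, labels: np.ndarray, rod_densities
) -> pd.DataFrame:
    """Per-rod HU statistics over all voxels of each rod label.

    Returns a DataFrame indexed by rod number with columns
    ``density, n_voxels, mean_hu, median_hu, sd_hu`` (sample SD; NaN for a
    single-voxel rod).
    """
    rod_densities = np.asarray(rod_densities, dtype=float)
    if rod_densities.size != 6:
        raise ValueError("expected six rod densities")
    if not np.all(np.diff(rod_densities) > 0):
        raise ValueError("rod densities must be strictly increasing")
    rows = []
    missing = []
    for k, rho in enumerate(rod_densities, start=1):
        sel = labels == rod_label(k)
        n = int(sel.sum())
        if n == 0:
            missing.append(LABEL_NAMES[rod_label(k)])
            continue
        hu = vol.data[sel].astype(float)
        rows.append(
            {
                "rod": k,
                "density": float(rho),
                "n_voxels": n,
                "mean_hu": float(hu.mean()),
                "median_hu": float(np.median(hu)),
                "sd_hu": float(hu.std(ddof=1)) if n > 1 else float("nan"),
            }
        )
    if missing:
        raise ValueError(f"rod labels missing from label volume: {missing}")
    return pd.DataFrame(rows).set_index("rod")


def fit_hu_to_density(rod_stats: pd.DataFrame) -> CalibrationModel:
    """OLS fit of known density on rod median HU."""
    hu = rod_stats["median_hu"].to_numpy(dtype=float)
    rho = rod_stats["density"].to_numpy(dtype=float)
    if hu.size < 2:
        raise ValueError("need at least two rods to fit a calibration")
    if np.ptp(hu) == 0:
        raise ValueError("degenerate calibration: all rod HU values equal")
    res = stats.linregress(hu, rho)
    r2 = float(res.rvalue**2)
    model = CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(r2, 1.0),
        n_rods=int(hu.size),
    )
    if model.r_squared < 0.99:
        logger.warning(
            "calibration fit r^2 = %.4f < 0.99; check rod segmentation",
            model.r_squared,
        )
    return model


def apply_calibration(vol: ImageVolume, model: CalibrationModel) -> np.ndarray:
    """Voxel-wise equivalent mineral density (g/cm^3), clamped at 0.

    Negative calibrated densities are clamped because the downstream ash
    density must be non-negative.
    """
    return model.density(vol.data)


def calibrate_from_ground_truth(vol, labels, rod_densities) -> CalibrationModel:
    """Convenience: rod stats + fit in one call (labels are an input)."""
    return fit_hu_to_density(extract_rod_stats(vol, labels, rod_densities))


def save_calibration(model: CalibrationModel, rod_stats: pd.DataFrame, path):
    payload = {
        "model": model.to_dict(),
        "rod_stats": rod_stats.reset_index().to_dict(orient="records"),
        "units": {"slope": "(g/cm^3)/HU", "intercept": "g/cm^3"},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
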