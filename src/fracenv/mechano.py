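"""Mechanobiological post-processing of the FE solution.

Per-element strain invariants (volumetric strain, octahedral shear strain,
hydrostatic pressure), tissue-differentiation classification of the fracture
gap against configurable strain/pressure limits, zone census, and
interfragmentary movement (IFM).

Sign convention: hydrostatic pressure is compression-positive,
p = -tr(sigma)/3.  Octahedral shear strain is computed from principal
strains, gamma_oct = (2/3) sqrt((e1-e2)^2 + (e2-e3)^2 + (e3-e1)^2).

The default zone limits follow the strain/pressure boundaries commonly
quoted for the mechanoregulation of fracture callus tissue: bony
(intramembranous) formation for distortional strains up to ~5% and
hydrostatic pressures within +-0.15 MPa, cartilage-mediated (endochondral)
formation for compressive pressures beyond 0.15 MPa with strains up to
~15%, and excessive connective-tissue stimulus beyond that.  An optional
low-stimulus band flags elements below the formation threshold (between
resorption and formation).  These limits are package defaults, fully
configurable; every report echoes the rule actually used.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .elasticity import FieldSolution
from .meshmat import TetMesh
from .volume import BONE, GAP

ZONE_RESORPTION = "resorption_band"
ZONE_INTRAMEMBRANOUS = "intramembranous_ossification"
ZONE_ENDOCHONDRAL = "endochondral_ossification"
ZONE_EXCESS = "connective_tissue_excess"
OSSIFICATION_ZONES = (ZONE_INTRAMEMBRANOUS, ZONE_ENDOCHONDRAL)


def _voigt_to_tensor(v: np.ndarray) -> np.ndarray:
    """(..., 6) engineering Voigt -> (..., 3, 3) tensor (shear halved)."""
    v = np.asarray(v, dtype=float)
    t = np.zeros(v.shape[:-1] + (3, 3))
    t[..., 0, 0], t[..., 1, 1], t[..., 2, 2] = v[..., 0], v[..., 1], v[..., 2]
    t[..., 0, 1] = t[..., 1, 0] = v[..., 3] / 2.0
    t[..., 1, 2] = t[..., 2, 1] = v[..., 4] / 2.0
    t[..., 0, 2] = t[..., 2, 0] = v[..., 5] / 2.0
    return t


def _as_strain_tensor(eps) -> np.ndarray:
    e = np.asarray(eps, dtype=float)
    if e.shape[-2:] == (3, 3):
        return e
    if e.shape[-1] == 6:
        return _voigt_to_tensor(e)
    raise ValueError("strain must be (..., 6) Voigt or (..., 3, 3)")


def volumetric_strain(eps) -> np.ndarray | float:
    """Trace of the strain tensor (relative volume change)."""
    t = _as_strain_tensor(eps)
    out = np.trace(t, axis1=-2, axis2=-1)
    return float(out) if np.ndim(out) == 0 else out


def octahedral_shear_strain(eps) -> np.ndarray | float:
    """Octahedral shear strain from principal strains (always >= 0)."""
    t = _as_strain_tensor(eps)
    e = np.linalg.eigvalsh(t)  # ascending principal strains
    e1, e2, e3 = e[..., 0], e[..., 1], e[..., 2]
    out = (2.0 / 3.0) * np.sqrt(
        (e1 - e2) ** 2 + (e2 - e3) ** 2 + (e3 - e1) ** 2
    )
    return float(out) if np.ndim(out) == 0 else out


def hydrostatic_pressure(sigma) -> np.ndarray | float:
    """Hydrostatic pressure, p = -tr(sigma)/3 (compression positive), MPa."""
    s = np.asarray(sigma, dtype=float)
    if s.shape[-2:] == (3, 3):
        tr = np.trace(s, axis1=-2, axis2=-1)
    elif s.shape[-1] == 6:
        tr = s[..., 0] + s[..., 1] + s[..., 2]
    else:
        raise ValueError("stress must be (..., 6) Voigt or (..., 3, 3)")
    out = -tr / 3.0
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class StrainInvariants:
    """Per-element mechanobiological stimuli."""

    eps_vol: np.ndarray  # dimensionless
    gamma_oct: np.ndarray  # dimensionless, >= 0
    p_hydro: np.ndarray  # MPa, compression positive

    @classmethod
    def from_solution(cls, sol: FieldSolution) -> "StrainInvariants":
        return cls(
            eps_vol=volumetric_strain(sol.strain),
            gamma_oct=octahedral_shear_strain(sol.strain),
            p_hydro=hydrostatic_pressure(sol.stress),
        )


@dataclass
class Zone:
    """Half-open box in the (gamma_oct, p_hydro) plane; first match wins."""

    name: str
    gamma_max: float = np.inf
    p_min: float = -np.inf  # MPa, compression positive
    p_max: float = np.inf

    def contains(self, gamma, p):
        return (gamma <= self.gamma_max) & (p >= self.p_min) & (p <= self.p_max)


@dataclass
class HealingZoneRule:
    """Ordered zone list; must end in a catch-all covering the plane."""

    zones: list[Zone]

    def __post_init__(self) -> None:
        if not self.zones:
            raise ValueError("rule needs at least one zone")
        last = self.zones[-1]
        if not (
            np.isinf(last.gamma_max)
            and np.isneginf(last.p_min)
            and np.isposinf(last.p_max)
        ):
            raise ValueError(
                "rule does not cover the stimulus plane: the last zone must "
                "be unbounded (catch-all)"
            )

    @property
    def zone_names(self) -> list[str]:
        return [z.name for z in self.zones]

    def to_dict(self) -> dict:
        return {"zones": [asdict(z) for z in self.zones]}


def default_rule(
    include_resorption_band: bool = False,
    intramembranous_strain: float = 0.05,
    intramembranous_pressure: float = 0.15,
    endochondral_strain: float = 0.15,
    low_stimulus_strain: float = 0.005,
    low_stimulus_pressure: float = 0.05,
) -> HealingZoneRule:
    """The package's default tissue-differentiation limits (see module doc)."""
    zones = []
    if include_resorption_band:
        zones.append(
            Zone(
                ZONE_RESORPTION,
                gamma_max=low_stimulus_strain,
                p_min=-low_stimulus_pressure,
                p_max=low_stimulus_pressure,
            )
        )
    zones.append(
        Zone(
            ZONE_INTRAMEMBRANOUS,
            gamma_max=intramembranous_strain,
            p_min=-intramembranous_pressure,
            p_max=intramembranous_pressure,
        )
    )
    zones.append(
        Zone(
            ZONE_ENDOCHONDRAL,
            gamma_max=endochondral_strain,
            p_min=intramembranous_pressure,
        )
    )
    zones.append(Zone(ZONE_EXCESS))
    return HealingZoneRule(zones)


def classify_elements(
    inv: StrainInvariants, rule: HealingZoneRule
) -> np.ndarray:
    """Deterministic first-match zone label per element (object array of
    zone names)."""
    gamma = np.asarray(inv.gamma_oct)
    p = np.asarray(inv.p_hydro)
    labels = np.empty(gamma.shape, dtype=object)
    unassigned = np.ones(gamma.shape, dtype=bool)
    for zone in rule.zones:
        hit = unassigned & zone.contains(gamma, p)
        labels[hit] = zone.name
        unassigned &= ~hit
    assert not unassigned.any(), "rule validation guarantees coverage"
    return labels


def zone_fractions(labels: np.ndarray, rule: HealingZoneRule) -> dict:
    """Zone census: counts, exact fractions, and integer headline percents.

    Headline percentages are rounded to the nearest integer (reporting
    style); exact fractions are retained.
    """
    labels = np.asarray(labels)
    total = int(labels.size)
    if total == 0:
        raise ValueError("no elements to tally")
    counts = {name: int((labels == name).sum()) for name in rule.zone_names}
    fractions = {k: v / total for k, v in counts.items()}
    assert abs(sum(fractions.values()) - 1.0) <= 1e-12
    return {
        "total": total,
        "counts": counts,
        "fractions": fractions,
        "headline_percent": {k: int(round(100 * v)) for k, v in
                             fractions.items()},
    }


def interfragmentary_movement(
    sol: FieldSolution,
    mesh: TetMesh,
    normal,
    gap_part: int = GAP,
    bone_part: int = BONE,
) -> tuple[float, float]:
    """Interfragmentary movement across the gap, (axial mm, shear mm).

    The two gap interfaces are the bone nodes shared with gap elements,
    split by the side of the fracture plane (plane through the gap centroid
    with the given normal).  IFM is the difference of the mean interface
    displacements, decomposed along (axial, absolute value) and
    perpendicular to (shear, magnitude) the normal.
    """
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    gap_el = mesh.element_part == gap_part
    bone_el = mesh.element_part == bone_part
    if not gap_el.any() or not bone_el.any():
        raise ValueError("gap interfaces not identifiable: missing parts")
    gap_nodes = np.unique(mesh.elements[gap_el])
    bone_nodes = np.unique(mesh.elements[bone_el])
    interface = np.intersect1d(gap_nodes, bone_nodes)
    if interface.size == 0:
        raise ValueError("gap interfaces not identifiable: gap does not "
                         "touch bone")
    center = mesh.nodes[gap_nodes].mean(axis=0)
    side = (mesh.nodes[interface] - center) @ n
    prox = interface[side > 0]
    dist = interface[side < 0]
    if prox.size == 0 or dist.size == 0:
        raise ValueError("gap interfaces not identifiable: one-sided contact")
    delta = sol.displacement[prox].mean(axis=0) - sol.displacement[dist].mean(
        axis=0
    )
    axial = float(np.abs(delta @ n))
    shear = float(np.linalg.norm(delta - (delta @ n) * n))
    return axial, shear


@dataclass
class MechanoReport:
    """Gap-tissue census plus construct-level summary quantities."""

    zone_summary: dict
    zone_labels: np.ndarray
    ifm_axial: float  # mm
    ifm_shear: float  # mm
    max_von_mises_by_part: dict
    rule: HealingZoneRule
    invariants: StrainInvariants | None = None

    def ossification_fraction(self) -> float:
        return sum(
            self.zone_summary["fractions"].get(z, 0.0)
            for z in OSSIFICATION_ZONES
        )

    def to_dict(self) -> dict:
        return {
            "zone_summary": self.zone_summary,
            "ifm_axial_mm": self.ifm_axial,
            "ifm_shear_mm": self.ifm_shear,
            "max_von_mises_by_part_MPa": {
                k: {"max_MPa": v[0], "element": v[1]}
                for k, v in self.max_von_mises_by_part.items()
            },
            "ossification_fraction": self.ossification_fraction(),
            "rule": self.rule.to_dict(),
            "pressure_sign_convention": "compression positive",
        }
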