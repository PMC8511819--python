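"""End-to-end orchestration: phantom -> calibration -> segmentation ->
mesh/materials -> elastic solve -> mechanobiological report.

A scenario is one treatment configuration (nail diameter, screws, load).
Paired scenarios (e.g. a failed 8 mm nail vs a 9 mm exchange nail) share the
phantom geometry and load case and differ only in implant parameters, so
their reports are directly comparable.

The default load case is an axial compressive force of
``load_factor x body mass x g`` (2.5 x body weight by default) spread over
the proximal face nodes, with the distal face fully fixed -- a standard
gait-peak surrogate, not a patient-derived load.

Implant peak stresses are compared against configurable material strength
constants (Ti alloy minimum yield 860 MPa / tensile 930 MPa); the comparison
is advisory reporting only and never alters the solve.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import (
    apply_calibration,
    extract_rod_stats,
    fit_hu_to_density,
    save_calibration,
)
from .elasticity import (
    LoadCase,
    assemble_stiffness,
    max_von_mises_by_part,
    nodes_on_plane,
    solve,
)
from .mechano import (
    HealingZoneRule,
    MechanoReport,
    StrainInvariants,
    classify_elements,
    default_rule,
    interfragmentary_movement,
    zone_fractions,
)
from .meshmat import MaterialCard, assign_materials, voxels_to_tets
from .phantom import PhantomSpec, gap_plane_normal, generate_phantom
from .segmentation import SegmentationParams, segment_volume
from .vtkio import write_vtu
from .volume import GAP, ImageVolume, write_volume

logger = logging.getLogger(__name__)

GRAVITY = 9.81  # m/s^2


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class ScenarioConfig:
    """One treatment scenario: phantom overrides, load, processing params."""

    name: str = "scenario"
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    body_mass_kg: float = 73.0
    load_factor: float = 2.5  # multiples of body weight at gait peak
    load_angle_deg: float = 10.0  # inclination from the shaft axis
    force_vector: tuple[float, float, float] | None = None  # N, overrides
    load_distribution: str = "equal"
    element_order: int = 1
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    material_card: MaterialCard = field(default_factory=MaterialCard)
    include_resorption_band: bool = False
    out_dir: str | None = None
    seed: int = 0

    def resolved_force(self) -> tuple[float, float, float]:
        """Gait-peak surrogate: ``load_factor x`` body weight, compressive,
        inclined ``load_angle_deg`` from the shaft axis (the knee reaction is
        never purely axial; the shear component engages nail bending over the
        working length)."""
        if self.force_vector is not None:
            return tuple(float(c) for c in self.force_vector)
        f = self.load_factor * self.body_mass_kg * GRAVITY
        a = np.deg2rad(self.load_angle_deg)
        return (f * float(np.sin(a)), 0.0, -f * float(np.cos(a)))

    def rule(self) -> HealingZoneRule:
        return default_rule(include_resorption_band=self.include_resorption_band)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["resolved_force_N"] = list(self.resolved_force())
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        d.pop("resolved_force_N", None)
        if "phantom" in d and isinstance(d["phantom"], dict):
            d["phantom"] = PhantomSpec(**d["phantom"])
        if "segmentation" in d and isinstance(d["segmentation"], dict):
            d["segmentation"] = SegmentationParams(**d["segmentation"])
        if "material_card" in d and isinstance(d["material_card"], dict):
            d["material_card"] = MaterialCard(**d["material_card"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunReport:
    """Final per-scenario report; JSON-serializable and timestamp-free."""

    scenario: str
    config_hash: str
    seed: int
    version: str
    calibration: dict
    mesh_info: dict
    mechano: dict
    strength_flags: dict
    solver: dict

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunReport":
        with open(path) as fh:
            return cls(**json.load(fh))


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(config: ScenarioConfig) -> RunReport:
    """Run all stages for one scenario; deterministic for a fixed seed."""
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    spec = config.phantom
    if spec.seed != config.seed:
        spec = PhantomSpec(**{**spec.to_dict(), "seed": config.seed})

    logger.info("[%s] generating phantom", config.name)
    vol, gt = _stage("phantom")(generate_phantom)(spec)
    if out:
        write_volume(vol, out / "volume.mha")
        write_volume(
            ImageVolume(gt.labels.astype(np.int16), vol.spacing, vol.origin),
            out / "labels_gt.mha",
        )
        (out / "phantom_spec.json").write_text(
            json.dumps(spec.to_dict(), indent=2, default=str)
        )

    logger.info("[%s] calibrating", config.name)
    rod_stats = _stage("calibration")(extract_rod_stats)(
        vol, gt.labels, spec.rod_densities
    )
    cal = _stage("calibration")(fit_hu_to_density)(rod_stats)
    density = apply_calibration(vol, cal)
    if out:
        save_calibration(cal, rod_stats, out / "calibration.json")

    logger.info("[%s] segmenting", config.name)
    rod_region = gt.labels >= 10  # rod fixtures are a known input, not anatomy
    masks, seg_labels = _stage("segmentation")(segment_volume)(
        vol, cal, config.segmentation, exclude=rod_region
    )
    if out:
        write_volume(
            ImageVolume(seg_labels.astype(np.int16), vol.spacing, vol.origin),
            out / "labels_seg.mha",
        )
        (out / "segmentation_provenance.json").write_text(
            json.dumps(masks.provenance, indent=2)
        )

    logger.info("[%s] meshing", config.name)
    mesh = _stage("meshing")(voxels_to_tets)(
        seg_labels, vol.spacing, order=config.element_order, origin=vol.origin
    )
    dens_vol = ImageVolume(density, vol.spacing, vol.origin)
    mats = _stage("materials")(assign_materials)(
        mesh, dens_vol, config.material_card
    )

    logger.info(
        "[%s] solving (%d elements, %d nodes)",
        config.name,
        mesh.n_elements,
        mesh.n_nodes,
    )
    zmin = mesh.nodes[:, 2].min()
    zmax = mesh.nodes[:, 2].max()
    loadcase = LoadCase(
        fixed_nodes=nodes_on_plane(mesh, 2, zmin),
        load_nodes=nodes_on_plane(mesh, 2, zmax),
        force=config.resolved_force(),
        distribution=config.load_distribution,
        description=(
            f"{config.load_factor} x body weight ({config.body_mass_kg} kg), "
            f"{config.load_angle_deg} deg from the shaft axis, on the "
            "proximal face; distal face fixed"
        ),
    )
    K = _stage("assembly")(assemble_stiffness)(mesh, mats)
    sol = _stage("solve")(solve)(K, loadcase, mesh, mats)

    logger.info("[%s] mechanobiological post-processing", config.name)
    rule = config.rule()
    inv = StrainInvariants.from_solution(sol)
    gap_sel = mesh.element_part == GAP
    gap_inv = StrainInvariants(
        eps_vol=inv.eps_vol[gap_sel],
        gamma_oct=inv.gamma_oct[gap_sel],
        p_hydro=inv.p_hydro[gap_sel],
    )
    zone_labels = _stage("classification")(classify_elements)(gap_inv, rule)
    summary = _stage("classification")(zone_fractions)(zone_labels, rule)
    ifm_axial, ifm_shear = _stage("ifm")(interfragmentary_movement)(
        sol, mesh, gap_plane_normal(spec)
    )
    max_vm = max_von_mises_by_part(sol, mesh)
    report_mech = MechanoReport(
        zone_summary=summary,
        zone_labels=zone_labels,
        ifm_axial=ifm_axial,
        ifm_shear=ifm_shear,
        max_von_mises_by_part=max_vm,
        rule=rule,
        invariants=gap_inv,
    )

    card = config.material_card
    implant_max = max_vm.get("implant", (0.0, -1))[0]
    strength_flags = {
        "implant_max_von_mises_MPa": implant_max,
        "yield_strength_MPa": card.yield_strength,
        "tensile_strength_MPa": card.tensile_strength,
        "exceeds_yield": bool(implant_max > card.yield_strength),
        "exceeds_tensile": bool(implant_max > card.tensile_strength),
        "note": "strength comparison is reporting only; it never alters "
        "the solve",
    }

    report = RunReport(
        scenario=config.name,
        config_hash=config.config_hash(),
        seed=config.seed,
        version=__version__,
        calibration=cal.to_dict(),
        mesh_info={
            "n_elements": mesh.n_elements,
            "n_nodes": mesh.n_nodes,
            "n_gap_elements": int(gap_sel.sum()),
            "element_order": mesh.order,
            "units": "mm, N, MPa",
        },
        mechano=report_mech.to_dict(),
        strength_flags=strength_flags,
        solver=sol.diagnostics,
    )
    if out:
        zone_code = np.zeros(mesh.n_elements, dtype=np.int64)
        names = rule.zone_names
        full_labels = classify_elements(inv, rule)
        for i, name in enumerate(names):
            zone_code[full_labels == name] = i
        write_vtu(
            mesh,
            out / "mesh.vtu",
            cell_data={
                "young_modulus_MPa": mats.young_modulus,
                "von_mises_MPa": sol.von_mises,
                "healing_zone": zone_code,
                "gamma_oct": inv.gamma_oct,
                "p_hydro_MPa": inv.p_hydro,
            },
            point_data={"displacement_mm": sol.displacement},
        )
        pd.DataFrame(
            {
                "element": np.flatnonzero(gap_sel),
                "eps_vol": gap_inv.eps_vol,
                "gamma_oct": gap_inv.gamma_oct,
                "p_hydro_MPa": gap_inv.p_hydro,
                "zone": zone_labels,
            }
        ).to_csv(out / "gap_elements.csv", index=False)
        report.save(out / "report.json")
    return report


def compare_scenarios(a: RunReport, b: RunReport) -> pd.DataFrame:
    """Side-by-side comparison table of two scenario reports."""

    def metrics(r: RunReport) -> dict:
        vm = {
            f"max_von_mises_{part}_MPa": v["max_MPa"]
            for part, v in r.mechano["max_von_mises_by_part_MPa"].items()
        }
        fr = {
            f"fraction_{z}": f
            for z, f in r.mechano["zone_summary"]["fractions"].items()
        }
        return {
            **vm,
            **fr,
            "ossification_fraction": r.mechano["ossification_fraction"],
            "ifm_axial_mm": r.mechano["ifm_axial_mm"],
            "ifm_shear_mm": r.mechano["ifm_shear_mm"],
            "exceeds_yield": float(r.strength_flags["exceeds_yield"]),
            "exceeds_tensile": float(r.strength_flags["exceeds_tensile"]),
        }

    ma, mb = metrics(a), metrics(b)
    keys = sorted(set(ma) | set(mb))
    rows = []
    for k in keys:
        va, vb = ma.get(k, np.nan), mb.get(k, np.nan)
        rows.append(
            {"metric": k, a.scenario: va, b.scenario: vb, "delta": vb - va}
        )
    return pd.DataFrame(rows).set_index("metric")


def default_scenario_pair(
    seed: int = 0, out_root: str | None = None
) -> tuple[ScenarioConfig, ScenarioConfig]:
    """The committed treatment pair: failed 8 mm nail vs 9 mm exchange nail.

    Identical phantom geometry, screws, and load; only the nail diameter
    differs.  The smaller nail leaves a wider free annulus at the locking
    screws, so the construct is more compliant and its nail is more highly
    stressed under the shared load.
    """
    base = PhantomSpec(seed=seed)
    failed = ScenarioConfig(
        name="failed_8mm",
        phantom=PhantomSpec(**{**base.to_dict(), "nail_diameter": 8.0}),
        seed=seed,
        out_dir=str(Path(out_root) / "failed_8mm") if out_root else None,
    )
    revision = ScenarioConfig(
        name="revision_9mm",
        phantom=base,
        seed=seed,
        out_dir=str(Path(out_root) / "revision_9mm") if out_root else None,
    )
    return failed, revision
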