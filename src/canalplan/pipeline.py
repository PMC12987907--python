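"""End-to-end orchestration: configuration, per-case pipeline and cohort
runs.

A case run executes: side normalization -> ROI crop -> outer-surface
wrap -> skull base + sigmoid surface -> entry region -> per-canal
centrelines and targets -> distance fields -> access maps -> mutual
three-trajectory optimization -> case report.  Every run serializes its
fully resolved configuration next to its outputs; all randomness flows
from the single config seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .anatomy import CANAL_MESH_NAMES, CANALS, AnatomyCase
from .centreline import extract_centreline, locate_targets
from .clearance import DrillProfile, build_distance_field
from .errors import CanalPlanError, ParameterError
from .feasibility import (
    case_report,
    cohort_summary,
    compute_access_map,
    fenestration_sweep,
    optimize_mutual,
)
from .surfaces import (
    build_entry_region,
    build_sigmoid_surface,
    crop_roi,
    extract_outer_surface,
    extract_skull_base,
    normalize_side,
    subtract_mesh,
)

log = logging.getLogger("canalplan")

OBSTRUCTION_SET = (
    "SCC_superior",
    "SCC_lateral",
    "SCC_posterior",
    "facial_nerve",
    "chorda_tympani",
    "lateral_skull_base",
    "sigmoid_sinus",
    "external_auditory_canal",
)


@dataclass
class PipelineConfig:
    """All analysis parameters.

    The clinical defaults mirror the planning setup: 0.1 mm voxel pitch
    for canal skeletonization, 0.125 mm distance-field spacing and path
    sampling, the stepped drill profile (0.5 / 0.6 / 1.25 mm), margin
    thresholds {0.5, 1, 2} mm, 80 deg maximum and 30 deg ideal canal
    entry angle, 2 mm fenestration offset, 12.5 mm pairwise entry
    constraint within a 15 mm mastoidectomy, and a 30 x 30 mm (+10 x 10)
    entry region sampled with 5000 points.  The problem-size knobs
    (``n_entry_points``, ``field_spacing``, ``outer_face_area``,
    ``sigmoid_directions``) may be coarsened for desk-scale runs via
    :meth:`coarse`.
    """

    voxel_pitch: float = 0.1  # mm, canal voxelization
    field_spacing: float = 0.125  # mm, distance-field grid
    sample_step: float = 0.125  # mm, along-trajectory sampling
    drill_tip_radius: float = 0.5
    drill_steps: tuple = ((4.0, 0.6), (14.0, 1.25))
    margin_thresholds: tuple = (0.5, 1.0, 2.0)  # mm
    max_angle: float = 80.0  # degrees
    ideal_angle: float = 30.0  # degrees
    fenestration_offset: float = 2.0  # mm from the electrode target
    max_pairwise: float = 12.5  # mm between mutual entry points
    mastoidectomy_diameter: float = 15.0  # mm
    entry_square: float = 30.0  # mm
    entry_extension: float = 10.0  # mm
    n_entry_points: int = 5000
    outer_face_area: float = 0.1  # mm^2 target for the outer-surface wrap
    sigmoid_alpha: float = 0.1
    sigmoid_directions: int = 256
    sigmoid_spacing: float = 0.5  # mm along the sinus centreline
    sweep_offsets: tuple = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)  # mm
    seed: int = 0

    @property
    def drill_profile(self) -> DrillProfile:
        return DrillProfile(tip_radius=self.drill_tip_radius, steps=self.drill_steps)

    @classmethod
    def coarse(cls, seed: int = 0, **overrides) -> "PipelineConfig":
        """Desk-scale preset: identical thresholds and drill geometry, but
        fewer entry points and coarser grids so a full cohort runs on a
        single CPU in minutes."""
        base = dict(
            n_entry_points=400,
            field_spacing=0.5,
            sample_step=0.25,
            outer_face_area=1.0,
            sigmoid_directions=96,
            sigmoid_spacing=1.0,
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["drill_steps"] = [list(s) for s in self.drill_steps]
        d["margin_thresholds"] = list(self.margin_thresholds)
        d["sweep_offsets"] = list(self.sweep_offsets)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["drill_steps"] = tuple(tuple(s) for s in d["drill_steps"])
        d["margin_thresholds"] = tuple(d["margin_thresholds"])
        d["sweep_offsets"] = tuple(d.get("sweep_offsets", (0, 1, 2, 3, 4, 5, 6)))
        return cls(**d)


def _stage(name: str, case_id: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.info("[%s] stage %-18s %6.1f s", case_id, name, dt)
                return False
            if isinstance(exc, CanalPlanError):
                exc.args = (f"stage {name!r} failed for case {case_id}: {exc}",)
                return False
            raise CanalPlanError(
                f"stage {name!r} failed for case {case_id}: {exc}"
            ) from exc

    return _Ctx()


def derive_surfaces(case: AnatomyCase, config: PipelineConfig) -> dict:
    """Side normalization, ROI crop, outer surface, skull base, sigmoid
    surface and entry region for one case."""
    case = normalize_side(case)
    out = {"case": case}
    with _stage("crop_roi", case.case_id):
        roi = crop_roi(case.meshes["temporal_bone"], case.inner_ear_centre)
    with _stage("outer_surface", case.case_id):
        outer = extract_outer_surface(roi, target_face_area=config.outer_face_area)
    with _stage("skull_base", case.case_id):
        skull_base = extract_skull_base(roi, case.inner_ear_centre)
    with _stage("sigmoid_surface", case.case_id):
        sigmoid = build_sigmoid_surface(
            case.sigmoid_centreline,
            roi,
            alpha=config.sigmoid_alpha,
            n_directions=config.sigmoid_directions,
            sample_spacing=config.sigmoid_spacing,
        )
        skull_base = subtract_mesh(skull_base, sigmoid)
    with _stage("entry_region", case.case_id):
        eac_centre = case.eac_centre
        if eac_centre is None:
            # fall back: centroid of the lateral-most slab of the ear canal
            eac = case.meshes["external_auditory_canal"]
            v = eac.vertices.view(np.ndarray)
            slab = v[v[:, 0] > v[:, 0].max() - 1.0]
            eac_centre = slab.mean(axis=0)
        region = build_entry_region(
            outer,
            eac_centre,
            n_points=config.n_entry_points,
            square=config.entry_square,
            extension=config.entry_extension,
            seed=config.seed,
        )
    out.update(
        roi=roi, outer=outer, skull_base=skull_base, sigmoid=sigmoid, region=region
    )
    return out


def build_fields(case: AnatomyCase, surfaces: dict, config: PipelineConfig) -> dict:
    """Distance fields for every obstacle on a shared corridor grid."""
    region = surfaces["region"]
    anchor_pts = np.vstack(
        [region.points]
        + [np.asarray(p, dtype=float)[None] for p in case.nerve_targets.values()]
    )
    pad = config.drill_profile.max_radius + 2.0
    lo = anchor_pts.min(axis=0) - pad
    hi = anchor_pts.max(axis=0) + pad
    meshes = {
        "SCC_superior": case.meshes["SCC_superior"],
        "SCC_lateral": case.meshes["SCC_lateral"],
        "SCC_posterior": case.meshes["SCC_posterior"],
        "facial_nerve": case.meshes["facial_nerve"],
        "chorda_tympani": case.meshes["chorda_tympani"],
        "external_auditory_canal": case.meshes["external_auditory_canal"],
        "lateral_skull_base": surfaces["skull_base"],
        "sigmoid_sinus": surfaces["sigmoid"],
    }
    fields = {}
    for name, mesh in meshes.items():
        with _stage(f"field:{name}", case.case_id):
            fields[name] = build_distance_field(
                mesh, spacing=config.field_spacing, bounds=(lo, hi), name=name
            )
    return fields


def obstacles_for(canal: str):
    """Obstacle names for one target canal: every structure except the
    canal being entered."""
    own = CANAL_MESH_NAMES[canal]
    return tuple(o for o in OBSTRUCTION_SET if o != own)


def run_case(
    case: AnatomyCase,
    config: PipelineConfig = None,
    outdir=None,
) -> tuple:
    """Run the full pipeline on one case.

    Returns ``(report, artifacts)`` where artifacts holds every
    intermediate product.  When ``outdir`` is given, the resolved config,
    access maps (CSV), mutual plan and report (JSON) are written there.
    """
    config = config or PipelineConfig()
    surfaces = derive_surfaces(case, config)
    case = surfaces["case"]  # side-normalized
    fields = build_fields(case, surfaces, config)
    region = surfaces["region"]
    profile = config.drill_profile
    centrelines, targets, maps = {}, {}, {}
    for canal in CANALS:
        with _stage(f"centreline:{canal}", case.case_id):
            centrelines[canal] = extract_centreline(
                case.canal_mesh(canal), voxel_pitch=config.voxel_pitch
            )
            targets[canal] = locate_targets(
                centrelines[canal],
                case.nerve_targets[canal],
                config.fenestration_offset,
            )
        with _stage(f"access_map:{canal}", case.case_id):
            maps[canal] = compute_access_map(
                region,
                targets[canal],
                fields,
                obstacles_for(canal),
                canal=canal,
                profile=profile,
                threshold=config.margin_thresholds[1],
                max_angle=config.max_angle,
                sample_step=config.sample_step,
            )
    with _stage("mutual_plan", case.case_id):
        plan = optimize_mutual(
            maps,
            max_pairwise=config.max_pairwise,
            ideal_angle=config.ideal_angle,
        )
    report = case_report(
        case.case_id,
        {thr: maps for thr in config.margin_thresholds},
        plan,
        ci_trajectory=case.ci_trajectory,
        thresholds=config.margin_thresholds,
        mastoidectomy_diameter=config.mastoidectomy_diameter,
    )
    artifacts = {
        **surfaces,
        "fields": fields,
        "centrelines": centrelines,
        "targets": targets,
        "maps": maps,
        "plan": plan,
        "report": report,
    }
    if outdir is not None:
        write_case_outputs(Path(outdir), config, artifacts)
    return report, artifacts


def write_case_outputs(outdir: Path, config: PipelineConfig, artifacts) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    for canal, amap in artifacts["maps"].items():
        amap.to_dataframe().to_csv(outdir / f"access_map_{canal}.csv", index=False)
    for canal, cl in artifacts.get("centrelines", {}).items():
        cl.to_dataframe().to_csv(outdir / f"centreline_{canal}.csv", index=False)
    targets = artifacts.get("targets")
    if targets:
        (outdir / "targets.json").write_text(
            json.dumps({c: t.to_dict() for c, t in targets.items()}, indent=2)
        )
    plan = artifacts["plan"]
    plan_payload = {
        "feasible": plan.feasible,
        "objective_deg2": plan.objective,
        "max_pairwise_mm": plan.max_pairwise,
        "enclosing_diameter_mm": plan.enclosing_diameter,
        "angles_deg": plan.angles,
        "margins_mm": plan.margins,
        "entry_indices": plan.entry_indices,
        "constraints": plan.constraints,
        "diagnostics": plan.diagnostics,
    }
    (outdir / "mutual_plan.json").write_text(json.dumps(plan_payload, indent=2))
    report = artifacts["report"]
    report_payload = {
        "case_id": report.case_id,
        "feasible": report.feasible,
        "enclosing_diameter_mm": report.enclosing_diameter,
        "per_canal": report.per_canal,
        "mutual": report.mutual,
    }
    (outdir / "report.json").write_text(json.dumps(report_payload, indent=2))


def run_cohort(
    cases,
    config: PipelineConfig = None,
    outdir=None,
) -> tuple:
    """Run every case, isolating per-case failures, and summarize.

    ``cases`` is an iterable of :class:`AnatomyCase` or a directory of
    saved case folders.  Returns ``(summary DataFrame, reports, errors)``.
    """
    config = config or PipelineConfig()
    if isinstance(cases, (str, Path)):
        root = Path(cases)
        case_dirs = sorted(d for d in root.iterdir() if (d / "landmarks.json").exists())
        cases = [AnatomyCase.load(d) for d in case_dirs]
    cases = list(cases)
    if len(cases) == 0:
        raise ParameterError("cohort contains no valid cases")
    reports, errors = [], {}
    for case in cases:
        try:
            case_out = None if outdir is None else Path(outdir) / case.case_id
            report, _ = run_case(case, config, outdir=case_out)
            reports.append(report)
        except Exception as exc:  # isolate per-case failures
            log.error("case %s failed: %s", case.case_id, exc)
            errors[case.case_id] = str(exc)
    if not reports:
        raise CanalPlanError(f"every case failed: {errors}")
    summary = cohort_summary(sorted(reports, key=lambda r: r.case_id))
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        summary.to_csv(Path(outdir) / "cohort_summary.csv", index=False)
        config.to_yaml(Path(outdir) / "config.yaml")
    return summary, reports, errors


def run_sweep(
    case: AnatomyCase,
    canal: str = "superior",
    config: PipelineConfig = None,
    offsets=None,
) -> pd.DataFrame:
    """Fenestration-site sweep along one canal for one case."""
    config = config or PipelineConfig()
    offsets = config.sweep_offsets if offsets is None else offsets
    surfaces = derive_surfaces(case, config)
    case = surfaces["case"]
    fields = build_fields(case, surfaces, config)
    cl = extract_centreline(case.canal_mesh(canal), voxel_pitch=config.voxel_pitch)
    return fenestration_sweep(
        cl,
        case.nerve_targets[canal],
        surfaces["region"],
        fields,
        obstacles_for(canal),
        offsets,
        canal=canal,
        profile=config.drill_profile,
        threshold=config.margin_thresholds[1],
        max_angle=config.max_angle,
        sample_step=config.sample_step,
    )
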