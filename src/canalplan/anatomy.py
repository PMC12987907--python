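"""Seeded synthetic temporal-bone anatomy.

Real planning cases come from segmented CT of the temporal bone; no such
dataset ships with this package, so this module generates anatomically
plausible stand-in cases with the geometric structure the downstream
analysis assumes:

* the three semicircular canals as hollow torus-arc tubes with an
  ampullary swelling at one end (lumen diameter ~1.0-1.2 mm);
* facial nerve and chorda tympani as thin tubes descending through the
  mastoid, anterior to the drill corridor;
* a cylindrical external auditory canal;
* a temporal-bone block whose superior face plays the lateral skull base,
  whose lateral face carries the drill entry region, and which contains a
  tubular sigmoid-sinus channel and optional spherical air-cell cavities;
* per-canal nerve stimulation targets at the ampullary ends, a sigmoid
  centreline, and a cochlear-implant reference trajectory.

Coordinate frame (right-ear convention): origin at the inner-ear centre,
+x lateral, +y anterior, +z superior, units mm.  Left-ear cases are exact
sagittal mirrors of the right-ear case generated from the same seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import trimesh
import yaml

from .errors import ParameterError
from .geometry import mirror_mesh, tube_along_curve

CANALS = ("superior", "lateral", "posterior")
CANAL_MESH_NAMES = {c: f"SCC_{c}" for c in CANALS}
STRUCTURES = (
    "SCC_superior",
    "SCC_lateral",
    "SCC_posterior",
    "facial_nerve",
    "chorda_tympani",
    "external_auditory_canal",
    "temporal_bone",
)


def _unit(v):
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ParameterError("zero-length direction vector")
    return v / n


@dataclass
class AnatomyParams:
    """Generation parameters for one synthetic temporal-bone case.

    Canal plane normals follow the canonical orientations: the lateral
    canal lies in a tilted axial plane, the superior canal in a
    near-sagittal plane and the posterior canal in a vertical plane facing
    anterolaterally.  ``ampulla_directions`` are in-plane hints selecting
    which arc end carries the ampulla.
    """

    side: str = "right"
    lumen_diameter: float = 1.1  # mm, internal canal height
    major_radius: float = 3.2  # mm, torus arc radius
    arc_span_deg: float = 246.0
    ampulla_bulge: float = 1.7  # radius multiplier at the ampullary end
    canal_normals: dict = field(
        default_factory=lambda: {
            "superior": tuple(_unit((0.93, 0.35, 0.10))),
            "lateral": tuple(_unit((0.0, -0.34, 0.94))),
            "posterior": tuple(_unit((0.70, 0.71, 0.05))),
        }
    )
    canal_centres: dict = field(
        default_factory=lambda: {
            "superior": (0.98, -0.19, 4.49),
            "lateral": (2.34, 0.08, -0.5),
            "posterior": (-1.2, -2.6, -1.8),
        }
    )
    ampulla_directions: dict = field(
        default_factory=lambda: {
            "superior": (0.0, 1.0, -0.3),
            "lateral": (0.5, 0.9, 0.0),
            "posterior": (0.2, 0.5, -0.9),
        }
    )
    nerve_radii: dict = field(
        default_factory=lambda: {"facial": 0.6, "chorda": 0.25}
    )
    eac_radius: float = 3.5
    eac_axis: tuple = (1.0, 0.0, 0.0)
    eac_centre: tuple = (9.0, 8.0, 0.0)  # midpoint of the canal cylinder
    eac_length: float = 15.0
    skull_base_height: float = 16.0  # z of the superior face at the lateral edge
    skull_base_medial_height: float = 9.0  # z of the superior face medially
    mastoid_lateral: float = 16.0  # x of the lateral bone face
    bone_min: tuple = (-8.0, -34.0, -20.0)
    bone_max_y: float = 20.0
    sigmoid_control_points: tuple = (
        (10.0, -22.0, 6.0),
        (8.0, -24.0, 1.0),
        (6.0, -22.0, -6.0),
        (4.0, -19.0, -12.0),
    )
    sigmoid_radius: float = 4.0
    n_air_cells: int = 6
    air_cell_radius_range: tuple = (0.8, 2.5)
    seed: int = 0

    def validate(self) -> "AnatomyParams":
        if self.side not in ("left", "right"):
            raise ParameterError(f"side must be 'left' or 'right', got {self.side!r}")
        if not 0.8 <= self.lumen_diameter <= 1.5:
            raise ParameterError(
                f"lumen_diameter must be within [0.8, 1.5] mm, got {self.lumen_diameter}"
            )
        for name in (
            "major_radius",
            "eac_radius",
            "sigmoid_radius",
            "arc_span_deg",
            "eac_length",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        for k, r in self.nerve_radii.items():
            if r <= 0:
                raise ParameterError(f"nerve_radii[{k!r}] must be positive")
        if self.n_air_cells < 0:
            raise ParameterError("n_air_cells must be >= 0")
        lo, hi = self.air_cell_radius_range
        if lo <= 0 or hi < lo:
            raise ParameterError("air_cell_radius_range must satisfy 0 < lo <= hi")
        for c in CANALS:
            n = np.asarray(self.canal_normals[c], dtype=float)
            if abs(np.linalg.norm(n) - 1.0) > 1e-3:
                raise ParameterError(f"canal_normals[{c!r}] must be a unit vector")
        return self

    def to_dict(self) -> dict:
        def conv(v):
            if isinstance(v, dict):
                return {k: conv(x) for k, x in v.items()}
            if isinstance(v, (tuple, list, np.ndarray)):
                return [conv(x) for x in v]
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        return {k: conv(v) for k, v in self.__dict__.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "AnatomyParams":
        def detuple(v):
            if isinstance(v, dict):
                return {k: detuple(x) for k, x in v.items()}
            if isinstance(v, list):
                return tuple(detuple(x) for x in v)
            return v

        return cls(**{k: detuple(v) for k, v in d.items()})


@dataclass
class AnatomyCase:
    """All per-ear geometry needed by the planning pipeline."""

    side: str
    meshes: dict  # name -> trimesh.Trimesh, keys = STRUCTURES
    sigmoid_centreline: np.ndarray  # (n, 3) ordered, mm
    nerve_targets: dict  # canal -> (3,) point
    inner_ear_centre: np.ndarray  # (3,)
    ci_trajectory: Optional[tuple] = None  # (entry point, unit direction)
    eac_centre: Optional[np.ndarray] = None  # ear-canal centre on the lateral surface
    case_id: str = "case"

    def validate(self) -> "AnatomyCase":
        if self.side not in ("left", "right"):
            raise ParameterError(f"unknown side {self.side!r}")
        missing = [s for s in STRUCTURES if s not in self.meshes]
        if missing:
            raise ParameterError(f"missing structure meshes: {missing}")
        for name, mesh in self.meshes.items():
            v = mesh.vertices.view(np.ndarray)
            if len(mesh.faces) == 0 or not np.all(np.isfinite(v)):
                raise ParameterError(f"mesh {name!r} is empty or non-finite")
        if sorted(self.nerve_targets) != sorted(CANALS):
            raise ParameterError("exactly three nerve targets required (one per canal)")
        for c in CANALS:
            target = np.asarray(self.nerve_targets[c], dtype=float)
            mesh = self.meshes[CANAL_MESH_NAMES[c]]
            d = np.linalg.norm(mesh.vertices.view(np.ndarray) - target, axis=1).min()
            if d > 3.0:
                raise ParameterError(
                    f"nerve target for {c} canal lies {d:.1f} mm from the canal "
                    "(must be within 3 mm of the ampullary end)"
                )
        return self

    def canal_mesh(self, canal: str) -> trimesh.Trimesh:
        return self.meshes[CANAL_MESH_NAMES[canal]]

    # -- I/O -------------------------------------------------------------

    def save(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, mesh in self.meshes.items():
            mesh.export(directory / f"{name}.ply")
        landmarks = {
            "side": self.side,
            "case_id": self.case_id,
            "sigmoid_centreline": np.asarray(self.sigmoid_centreline).tolist(),
            "nerve_targets": {
                c: np.asarray(p).tolist() for c, p in self.nerve_targets.items()
            },
            "inner_ear_centre": np.asarray(self.inner_ear_centre).tolist(),
            "eac_centre": None
            if self.eac_centre is None
            else np.asarray(self.eac_centre).tolist(),
            "ci_trajectory": None
            if self.ci_trajectory is None
            else {
                "entry": np.asarray(self.ci_trajectory[0]).tolist(),
                "direction": np.asarray(self.ci_trajectory[1]).tolist(),
            },
        }
        (directory / "landmarks.json").write_text(json.dumps(landmarks, indent=2))
        return directory

    @classmethod
    def load(cls, directory) -> "AnatomyCase":
        directory = Path(directory)
        landmarks = json.loads((directory / "landmarks.json").read_text())
        meshes = {}
        for name in STRUCTURES:
            path = directory / f"{name}.ply"
            if not path.exists():
                path = directory / f"{name}.stl"
            meshes[name] = trimesh.load_mesh(path, process=False)
        ci = landmarks.get("ci_trajectory")
        return cls(
            side=landmarks["side"],
            meshes=meshes,
            sigmoid_centreline=np.asarray(landmarks["sigmoid_centreline"], dtype=float),
            nerve_targets={
                c: np.asarray(p, dtype=float)
                for c, p in landmarks["nerve_targets"].items()
            },
            inner_ear_centre=np.asarray(landmarks["inner_ear_centre"], dtype=float),
            ci_trajectory=None
            if ci is None
            else (
                np.asarray(ci["entry"], dtype=float),
                np.asarray(ci["direction"], dtype=float),
            ),
            eac_centre=None
            if landmarks.get("eac_centre") is None
            else np.asarray(landmarks["eac_centre"], dtype=float),
            case_id=landmarks.get("case_id", directory.name),
        )


# ---------------------------------------------------------------------------
# construction helpers


def _plane_basis(normal, ref):
    """In-plane orthonormal basis (u, v) of the plane with the given normal;
    u points along the projection of ``ref`` into the plane."""
    n = _unit(normal)
    u = np.asarray(ref, dtype=float) - np.dot(ref, n) * n
    nu = np.linalg.norm(u)
    if nu < 1e-8:
        fallback = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(fallback, n)) > 0.9:
            fallback = np.array([0.0, 1.0, 0.0])
        u = fallback - np.dot(fallback, n) * n
        nu = np.linalg.norm(u)
    u = u / nu
    v = np.cross(n, u)
    return u, v


def _canal_curve(params: AnatomyParams, canal: str, n_samples: int = None):
    """Analytic centreline of one canal (torus arc) plus its radius profile.

    The curve starts at the ampullary end.  Returns (points, radii).
    """
    centre = np.asarray(params.canal_centres[canal], dtype=float)
    normal = _unit(params.canal_normals[canal])
    u, v = _plane_basis(normal, params.ampulla_directions[canal])
    R = params.major_radius
    span = np.radians(params.arc_span_deg)
    # canals loop posteriorly away from their ampullae: pick the in-plane
    # orientation whose arc midpoint lies further posterior
    mid = span / 2.0
    if (np.cos(mid) * u + np.sin(mid) * v)[1] > (
        np.cos(mid) * u - np.sin(mid) * v
    )[1]:
        v = -v
    if n_samples is None:
        n_samples = max(24, int(np.ceil(R * span / 0.25)))
    t = np.linspace(0.0, span, n_samples)
    pts = centre + R * (np.cos(t)[:, None] * u + np.sin(t)[:, None] * v)
    r0 = params.lumen_diameter / 2.0
    s = R * t  # arc length from the ampullary end
    radii = r0 * (1.0 + (params.ampulla_bulge - 1.0) * np.exp(-((s / 1.2) ** 2)))
    return pts, radii


def _spline_through(points, spacing=0.4):
    """Densified smooth polyline through control points (Catmull-Rom-ish via
    cubic interpolation on chord length)."""
    from scipy.interpolate import CubicSpline

    points = np.asarray(points, dtype=float)
    chord = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(points, axis=0), axis=1))]
    )
    cs = CubicSpline(chord, points, axis=0)
    n = max(2, int(np.ceil(chord[-1] / spacing)) + 1)
    return cs(np.linspace(0.0, chord[-1], n))


def _bone_block(params: AnatomyParams, rng) -> tuple:
    """Temporal-bone surface soup: outer block + sigmoid channel wall +
    air-cell cavity walls (inward-facing)."""
    bmin = np.asarray(params.bone_min, dtype=float)
    x1, y1 = params.mastoid_lateral, params.bone_max_y
    z_lat, z_med = params.skull_base_height, params.skull_base_medial_height
    # block with a superior face sloping down medially (middle fossa floor
    # approaches the labyrinth medially; laterally the squama rises)
    corners = np.array(
        [
            [bmin[0], bmin[1], bmin[2]],
            [bmin[0], y1, bmin[2]],
            [x1, bmin[1], bmin[2]],
            [x1, y1, bmin[2]],
            [bmin[0], bmin[1], z_med],
            [bmin[0], y1, z_med],
            [x1, bmin[1], z_lat],
            [x1, y1, z_lat],
        ]
    )
    box = trimesh.Trimesh(vertices=corners, process=False).convex_hull
    box = box.subdivide_to_size(2.0, max_iter=12)
    parts = [box]
    # sigmoid channel: a tube cavity grooving the posterior mastoid; the
    # channel extends past the annotated centreline (as the real sinus does)
    sig_line = _spline_through(params.sigmoid_control_points, spacing=0.8)
    t0 = sig_line[0] - sig_line[1]
    t1 = sig_line[-1] - sig_line[-2]
    t0 /= np.linalg.norm(t0)
    t1 /= np.linalg.norm(t1)
    extended = np.vstack([sig_line[0] + 1.5 * t0, sig_line, sig_line[-1] + 1.5 * t1])
    channel = tube_along_curve(extended, params.sigmoid_radius, n_circ=24)
    channel.invert()  # cavity wall faces inward
    parts.append(channel)
    # air cells: spherical cavities in the mastoid interior
    lo, hi = params.air_cell_radius_range
    for _ in range(params.n_air_cells):
        centre = rng.uniform([8.0, -16.0, -10.0], [13.0, 2.0, 4.0])
        radius = rng.uniform(lo, hi)
        cell = trimesh.creation.icosphere(subdivisions=2, radius=radius)
        cell.apply_translation(centre)
        cell.invert()
        parts.append(cell)
    bone = trimesh.util.concatenate(parts)
    return bone, sig_line


def generate_case(params: AnatomyParams, case_id: str = "case") -> AnatomyCase:
    """Generate one synthetic temporal-bone case.

    Deterministic given ``params`` (including its seed); a left-sided case
    is the exact sagittal mirror of the right-sided case from the same
    parameters.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    meshes = {}
    nerve_targets = {}
    for canal in CANALS:
        pts, radii = _canal_curve(params, canal)
        meshes[CANAL_MESH_NAMES[canal]] = tube_along_curve(pts, radii, n_circ=16)
        # stimulation target: on the canal axis just inside the ampullary end
        nerve_targets[canal] = pts[2].copy()
    facial_pts = _spline_through(
        [(4.5, 3.8, 9.0), (6.0, 3.6, 2.0), (7.0, 3.6, -5.0), (8.0, 3.4, -13.0)]
    )
    meshes["facial_nerve"] = tube_along_curve(
        facial_pts, params.nerve_radii["facial"], n_circ=12
    )
    chorda_pts = _spline_through(
        [(7.7, 3.6, -12.0), (6.2, 4.6, -6.0), (4.8, 4.8, -2.8)]
    )
    meshes["chorda_tympani"] = tube_along_curve(
        chorda_pts, params.nerve_radii["chorda"], n_circ=10
    )
    eac_axis = _unit(params.eac_axis)
    eac_mid = np.asarray(params.eac_centre, dtype=float)
    half = params.eac_length / 2.0
    eac_line = np.linspace(eac_mid - half * eac_axis, eac_mid + half * eac_axis, 20)
    meshes["external_auditory_canal"] = tube_along_curve(
        eac_line, params.eac_radius, n_circ=24
    )
    bone, sig_line = _bone_block(params, rng)
    meshes["temporal_bone"] = bone
    # ear-canal centre on the lateral bone face (entry-region anchor)
    eac_centre_surface = np.array(
        [params.mastoid_lateral, params.eac_centre[1], params.eac_centre[2]]
    )
    ci_entry = np.array([params.mastoid_lateral, 6.0, -2.0])
    ci_dir = _unit(np.array([0.0, 5.0, -3.0]) - ci_entry)
    case = AnatomyCase(
        side="right",
        meshes=meshes,
        sigmoid_centreline=sig_line,
        nerve_targets=nerve_targets,
        inner_ear_centre=np.zeros(3),
        ci_trajectory=(ci_entry, ci_dir),
        eac_centre=eac_centre_surface,
        case_id=case_id,
    )
    if params.side == "left":
        case = mirror_case(case)
        case.side = "left"
    return case


def mirror_case(case: AnatomyCase) -> AnatomyCase:
    """Reflect a case about the sagittal plane through its inner-ear centre.

    Applying it twice restores the original coordinates; the side label is
    toggled.  Triangle winding is flipped so outward normals survive.
    """
    px = float(case.inner_ear_centre[0])

    def refl_pt(p):
        p = np.asarray(p, dtype=float).copy()
        p[..., 0] = 2.0 * px - p[..., 0]
        return p

    def refl_dir(d):
        d = np.asarray(d, dtype=float).copy()
        d[..., 0] = -d[..., 0]
        return d

    return AnatomyCase(
        side="right" if case.side == "left" else "left",
        meshes={n: mirror_mesh(m, px) for n, m in case.meshes.items()},
        sigmoid_centreline=refl_pt(case.sigmoid_centreline),
        nerve_targets={c: refl_pt(p) for c, p in case.nerve_targets.items()},
        inner_ear_centre=case.inner_ear_centre.copy(),
        ci_trajectory=None
        if case.ci_trajectory is None
        else (refl_pt(case.ci_trajectory[0]), refl_dir(case.ci_trajectory[1])),
        eac_centre=None if case.eac_centre is None else refl_pt(case.eac_centre),
        case_id=case.case_id,
    )


def _perturb(base: AnatomyParams, rng, side: str, seed: int) -> AnatomyParams:
    """Seeded per-case variation: +-10% sizes, +-10 degree orientation jitter,
    sigmoid position jitter (+-1 mm laterally, +-3 mm otherwise)."""
    scale = rng.uniform(0.9, 1.1)
    lumen = float(np.clip(base.lumen_diameter * rng.uniform(0.9, 1.1), 0.8, 1.5))

    def jitter_normal(n):
        axis = _unit(rng.normal(size=3))
        angle = np.radians(rng.uniform(-10.0, 10.0))
        n = np.asarray(n, dtype=float)
        n = (
            n * np.cos(angle)
            + np.cross(axis, n) * np.sin(angle)
            + axis * np.dot(axis, n) * (1 - np.cos(angle))
        )
        return tuple(_unit(n))

    # anisotropic jitter keeps the sinus channel interior to the bone block
    sig_off = np.array(
        [rng.uniform(-1.0, 1.0), rng.uniform(-3.0, 3.0), rng.uniform(-2.0, 2.0)]
    )
    return replace(
        base,
        side=side,
        seed=seed,
        lumen_diameter=lumen,
        major_radius=base.major_radius * scale,
        canal_normals={c: jitter_normal(n) for c, n in base.canal_normals.items()},
        sigmoid_control_points=tuple(
            tuple(np.asarray(p) + sig_off) for p in base.sigmoid_control_points
        ),
    )


def generate_cohort(
    n: int, base_params: AnatomyParams = None, seed: int = 0
) -> list:
    """Generate ``n`` seeded cases with inter-case variation and a mix of
    left and right sides."""
    if n < 1:
        raise ParameterError(f"cohort size must be >= 1, got {n}")
    if base_params is None:
        base_params = AnatomyParams()
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n):
        case_seed = int(rng.integers(0, 2**31 - 1))
        side = "left" if rng.random() < 0.5 else "right"
        params = _perturb(base_params, rng, side, case_seed)
        cases.append(generate_case(params, case_id=f"case_{i:03d}"))
    return cases


def save_cohort(cases, directory, params: AnatomyParams = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for case in cases:
        case.save(directory / case.case_id)
    if params is not None:
        (directory / "params.yaml").write_text(yaml.safe_dump(params.to_dict()))
    return directory
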