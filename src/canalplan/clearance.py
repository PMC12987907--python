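"""Signed distance fields, stepped-drill clearance, entry angles and the
idealized exposed-lumen-area model.

The drill used for keyhole access has a stepped profile: a 0.5 mm tip
radius widening to 0.6 mm at 4 mm and to 1.25 mm at 14 mm behind the tip.
Clearance along a candidate trajectory is the interpolated distance to an
obstacle's surface minus the local drill radius; the safety margin of the
trajectory is the minimum clearance over its path and over all obstacles.

The exposed-area model quantifies how much canal wall a spherical-tipped
drill removes when it enters an idealized straight cylindrical lumen at a
given angle, stopping with the tip centre on the canal axis: tangential
approaches expose an elongated strip, right-angled approaches a near
circle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import trimesh
from scipy.interpolate import RegularGridInterpolator

from .errors import GeometryError, OutOfBoundsError, RangeError
from .geometry import MeshDistance

__all__ = [
    "DrillProfile",
    "DistanceField",
    "Trajectory",
    "ClearanceReport",
    "drill_radius",
    "build_distance_field",
    "trajectory_clearance",
    "entry_angle",
    "exposed_area",
]


@dataclass(frozen=True)
class DrillProfile:
    """Piecewise-constant drill radius as a function of distance from the
    tip: ``tip_radius`` for s < first threshold, then each step's radius
    from its threshold on (half-open; the radius jumps AT the threshold)."""

    tip_radius: float = 0.5
    steps: tuple = ((4.0, 0.6), (14.0, 1.25))

    def __post_init__(self):
        radii = [self.tip_radius] + [r for _, r in self.steps]
        thresholds = [t for t, _ in self.steps]
        if any(r <= 0 for r in radii) or any(t <= 0 for t in thresholds):
            raise RangeError("drill radii and step thresholds must be positive")
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise RangeError("drill radii must be strictly increasing")
        if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
            raise RangeError("step thresholds must be strictly increasing")

    def radius_at(self, s):
        """Drill radius at distance ``s`` from the tip (vectorized)."""
        s = np.asarray(s, dtype=float)
        if np.any(s < 0):
            raise RangeError("distance from tip must be >= 0")
        thresholds = np.array([t for t, _ in self.steps])
        radii = np.array([self.tip_radius] + [r for _, r in self.steps])
        return radii[np.searchsorted(thresholds, s, side="right")]

    @property
    def max_radius(self) -> float:
        return self.steps[-1][1] if self.steps else self.tip_radius


def drill_radius(s, profile: DrillProfile = DrillProfile()):
    """Drill radius at distance-from-tip ``s`` (mm)."""
    out = profile.radius_at(s)
    return float(out) if np.isscalar(s) or np.ndim(s) == 0 else out


@dataclass
class DistanceField:
    """Distance to one structure's surface sampled on a regular grid.

    Values are signed (negative inside) for watertight structures,
    unsigned for open surfaces.  Off-node queries use trilinear
    interpolation; queries outside the grid raise
    :class:`OutOfBoundsError` rather than extrapolating.
    """

    origin: np.ndarray
    spacing: float
    values: np.ndarray  # (nx, ny, nz)
    name: str = ""
    _interp: Optional[RegularGridInterpolator] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self):
        if self.spacing <= 0:
            raise RangeError("grid spacing must be positive")
        axes = [
            self.origin[i] + self.spacing * np.arange(self.values.shape[i])
            for i in range(3)
        ]
        self._interp = RegularGridInterpolator(
            axes, self.values, method="linear", bounds_error=True
        )

    def query(self, points) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        try:
            return self._interp(points)
        except ValueError as exc:
            raise OutOfBoundsError(
                f"query outside distance-field grid for {self.name!r}: {exc}"
            ) from exc

    # -- cache I/O (binary grid + JSON header) ---------------------------

    def save(self, path) -> None:
        import json
        from pathlib import Path

        path = Path(path)
        header = {
            "origin": self.origin.tolist(),
            "spacing": self.spacing,
            "shape": list(self.values.shape),
            "name": self.name,
        }
        path.with_suffix(".json").write_text(json.dumps(header))
        self.values.astype(np.float32).tofile(path.with_suffix(".f32"))

    @classmethod
    def load(cls, path) -> "DistanceField":
        import json
        from pathlib import Path

        path = Path(path)
        header = json.loads(path.with_suffix(".json").read_text())
        values = np.fromfile(path.with_suffix(".f32"), dtype=np.float32).reshape(
            header["shape"]
        ).astype(float)
        return cls(
            origin=np.asarray(header["origin"], dtype=float),
            spacing=header["spacing"],
            values=values,
            name=header["name"],
        )


def build_distance_field(
    structure: trimesh.Trimesh,
    spacing: float = 0.125,
    bounds=None,
    name: str = "",
) -> DistanceField:
    """Sample the exact point-to-surface distance of ``structure`` on a
    regular grid (node values exact; off-node trilinear)."""
    if len(structure.faces) == 0:
        raise GeometryError("cannot build a distance field for an empty mesh")
    if bounds is None:
        bounds = (structure.bounds[0] - 2.0, structure.bounds[1] + 2.0)
    lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
    md = MeshDistance(structure)
    values = md.grid_signed_distance(lo, spacing, shape).reshape(shape)
    return DistanceField(origin=lo, spacing=spacing, values=values, name=name)


@dataclass
class Trajectory:
    """Straight drill path from a mastoid entry point to a fenestration
    site; the drill tip leads at the fenestration end."""

    entry: np.ndarray
    fenestration: np.ndarray

    def __post_init__(self):
        self.entry = np.asarray(self.entry, dtype=float)
        self.fenestration = np.asarray(self.fenestration, dtype=float)
        self.length = float(np.linalg.norm(self.fenestration - self.entry))
        if self.length <= 0:
            raise RangeError("trajectory has zero length")
        self.direction = (self.fenestration - self.entry) / self.length


@dataclass
class ClearanceReport:
    """Per-obstacle minimum clearances along one trajectory.

    ``per_obstacle`` maps obstacle name to (minimum clearance mm, arc
    length from the entry point at which it occurs).  The safety margin is
    the minimum clearance over all obstacles.
    """

    per_obstacle: dict
    safety_margin: float
    margin_location: float  # arc length (from entry) of the overall minimum

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"obstacle": name, "min_clearance_mm": c, "at_arc_length_mm": s}
                for name, (c, s) in self.per_obstacle.items()
            ]
        )


def trajectory_clearance(
    traj: Trajectory,
    fields,
    profile: DrillProfile = DrillProfile(),
    sample_step: float = 0.125,
) -> ClearanceReport:
    """Minimum clearance of a stepped drill along a trajectory.

    ``fields`` maps obstacle names to :class:`DistanceField`s.  Clearance
    at a sample is the interpolated surface distance minus the drill
    radius at that sample's distance from the tip (the tip leads at the
    fenestration end).  Negative clearance means collision; it is never
    clipped.
    """
    n = max(2, int(np.ceil(traj.length / sample_step)) + 1)
    s = np.linspace(0.0, traj.length, n)  # arc length from entry
    pts = traj.entry[None, :] + s[:, None] * traj.direction[None, :]
    radius = profile.radius_at(traj.length - s)  # distance from tip end
    per = {}
    best = (np.inf, 0.0)
    for name, f in fields.items():
        clearance = f.query(pts) - radius
        i = int(clearance.argmin())
        per[name] = (float(clearance[i]), float(s[i]))
        if clearance[i] < best[0]:
            best = (float(clearance[i]), float(s[i]))
    if not per:
        raise GeometryError("no obstacle fields supplied")
    return ClearanceReport(
        per_obstacle=per, safety_margin=best[0], margin_location=best[1]
    )


def entry_angle(traj: Trajectory, targets) -> float:
    """Canal entry angle (degrees) between the drill direction and the
    ampulla-directed centreline tangent at the fenestration site.

    0 deg is a perfectly tangential anterograde approach, 90 deg a
    right-angled entry, 180 deg retrograde.
    """
    tangent = np.asarray(targets.tangent, dtype=float)
    nt = np.linalg.norm(tangent)
    if nt < 1e-12:
        raise GeometryError("degenerate (zero) tangent at the fenestration site")
    cosang = np.dot(traj.direction, tangent / nt)
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _swept_distance(pts, tip_centre, drill_dir, tip_radius):
    """Distance of points to the drill's swept volume axis: the ray from
    the tip centre backward along the drill direction."""
    rel = pts - tip_centre
    proj = rel @ (-drill_dir)  # >0 behind the tip
    proj_clamped = np.maximum(proj, 0.0)
    closest = tip_centre[None, :] - proj_clamped[:, None] * drill_dir[None, :]
    return np.linalg.norm(pts - closest, axis=1)


def exposed_area(
    theta_deg: float,
    canal_lumen_diameter: float = 1.1,
    drill_tip_radius: float = 0.5,
    rel_tol: float = 0.01,
    n_start: int = 96,
) -> float:
    """Canal-wall area (mm^2) removed by the drill in the idealized
    geometry: straight cylindrical lumen, drill modelled as a cylinder
    with a hemispherical tip entering at ``theta_deg`` to the canal axis
    and stopping with its tip centre on the axis.

    Computed by sampling the lumen wall and testing containment in the
    swept drill volume, refined until the area changes by less than
    ``rel_tol`` between successive grid doublings.
    """
    if not 0.0 < theta_deg <= 90.0:
        raise RangeError(f"entry angle must be in (0, 90] degrees, got {theta_deg}")
    rc = canal_lumen_diameter / 2.0
    rt = drill_tip_radius
    theta = np.radians(theta_deg)
    # canal axis along x; drill direction in the x-z plane, tip at origin
    drill_dir = np.array([np.cos(theta), 0.0, -np.sin(theta)])
    half_extent = rt / np.sin(theta) + rt + 2.0 * rc
    area = None
    n = n_start
    for _ in range(8):
        x = np.linspace(-half_extent, half_extent, n)
        phi = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        X, P = np.meshgrid(x, phi, indexing="ij")
        pts = np.column_stack(
            [X.ravel(), rc * np.cos(P).ravel(), rc * np.sin(P).ravel()]
        )
        d = _swept_distance(pts, np.zeros(3), drill_dir, rt)
        inside = d <= rt
        cell = (x[1] - x[0]) * (rc * (phi[1] - phi[0]))
        new_area = float(inside.sum() * cell)
        if area is not None and area > 0 and abs(new_area - area) / area < rel_tol:
            return new_area
        area = new_area
        n *= 2
    return area
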