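"""Canal centreline extraction and drill-target placement.

The centreline of a semicircular canal is recovered by voxelizing the
canal mesh on a fine grid (0.1 mm), 3-D thinning with the method of Lee,
ordering the skeleton voxels along their longest path, and smoothing with
a cubic spline.  The electrode target is the centreline point closest to
the annotated nerve-stimulation target; the fenestration site sits a
fixed arc-length offset (default 2 mm) away from the ampulla.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import interpolate
from skimage.morphology import skeletonize

from .errors import RangeError, TopologyError

__all__ = ["Centreline", "CanalTargets", "extract_centreline", "locate_targets"]


@dataclass
class Centreline:
    """Arc-length parameterized canal axis.

    ``points`` are ordered samples (spacing <= 0.2 mm), ``s`` the strictly
    increasing arc-length parameter starting at 0, ``tangents`` unit
    tangents per sample.
    """

    points: np.ndarray
    s: np.ndarray
    tangents: np.ndarray

    @property
    def length(self) -> float:
        return float(self.s[-1])

    def point_at(self, s) -> np.ndarray:
        s = np.clip(s, 0.0, self.length)
        out = np.empty(3)
        for c in range(3):
            out[c] = np.interp(s, self.s, self.points[:, c])
        return out

    def tangent_at(self, s) -> np.ndarray:
        s = np.clip(s, 0.0, self.length)
        out = np.empty(3)
        for c in range(3):
            out[c] = np.interp(s, self.s, self.tangents[:, c])
        n = np.linalg.norm(out)
        return out / n if n > 0 else out

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "s_mm": self.s,
                "x": self.points[:, 0],
                "y": self.points[:, 1],
                "z": self.points[:, 2],
                "tx": self.tangents[:, 0],
                "ty": self.tangents[:, 1],
                "tz": self.tangents[:, 2],
            }
        )


@dataclass
class CanalTargets:
    """Electrode target and fenestration site on one canal."""

    electrode_target: np.ndarray
    fenestration_site: np.ndarray
    tangent: np.ndarray  # unit, oriented from fenestration site toward ampulla
    offset: float  # arc length between the two points, mm

    def validate(self, centreline: Centreline) -> "CanalTargets":
        for p in (self.electrode_target, self.fenestration_site):
            d = np.linalg.norm(centreline.points - p, axis=1).min()
            if d > 0.1:
                raise RangeError(f"target point lies {d:.3f} mm off the centreline")
        if self.offset < 0:
            raise RangeError("offset must be >= 0")
        return self

    def to_dict(self) -> dict:
        return {
            "electrode_target": np.asarray(self.electrode_target).tolist(),
            "fenestration_site": np.asarray(self.fenestration_site).tolist(),
            "tangent": np.asarray(self.tangent).tolist(),
            "offset_mm": float(self.offset),
        }


def _longest_path(voxels: np.ndarray):
    """Longest geodesic path through 26-connected skeleton voxels
    (double BFS); returns ordered voxel indices along the path."""
    from collections import deque

    index = {tuple(v): i for i, v in enumerate(voxels)}
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    nbrs = [[] for _ in range(len(voxels))]
    for i, v in enumerate(voxels):
        t = tuple(v)
        for o in offsets:
            j = index.get((t[0] + o[0], t[1] + o[1], t[2] + o[2]))
            if j is not None:
                nbrs[i].append(j)

    def bfs(start):
        parent = {start: -1}
        order = deque([start])
        last = start
        while order:
            cur = order.popleft()
            last = cur
            for j in nbrs[cur]:
                if j not in parent:
                    parent[j] = cur
                    order.append(j)
        return last, parent

    a, _ = bfs(0)
    b, parent = bfs(a)
    path = []
    cur = b
    while cur != -1:
        path.append(cur)
        cur = parent[cur]
    return path


def _extend_to_surface(points, mesh, step: float = 0.05, max_extend: float = 1.5):
    """Extend a curve at both ends along its end tangents until just inside
    the canal surface (thinning erodes skeleton ends near the end caps)."""
    from .geometry import MeshDistance

    md = MeshDistance(mesh)
    out = points
    for end in (0, -1):
        p = out[0] if end == 0 else out[-1]
        q = out[1] if end == 0 else out[-2]
        t = p - q
        t /= np.linalg.norm(t) + 1e-12
        ext = []
        for i in range(1, int(max_extend / step) + 1):
            cand = p + i * step * t
            d = md.signed_distance(cand[None])[0]
            if d > -0.5 * step:  # reached (or crossed) the surface
                break
            ext.append(cand)
        if ext:
            ext = np.asarray(ext)
            out = (
                np.vstack([ext[::-1], out]) if end == 0 else np.vstack([out, ext])
            )
    return out


def extract_centreline(
    canal: trimesh.Trimesh,
    voxel_pitch: float = 0.1,
    resample_step: float = 0.1,
    max_spline_deviation: float = 0.1,
) -> Centreline:
    """Extract the smoothed, arc-length parameterized canal centreline.

    Raises :class:`TopologyError` when the skeleton is empty or so branched
    that no single path covers at least half of its voxels.
    """
    vg = canal.voxelized(voxel_pitch).fill()
    matrix = np.asarray(vg.matrix)
    if matrix.sum() == 0:
        raise TopologyError("voxelization produced an empty volume")
    skel = skeletonize(matrix, method="lee")
    voxels = np.argwhere(skel)
    if len(voxels) == 0:
        raise TopologyError("skeleton is empty")
    if len(voxels) < 4:
        raise TopologyError("skeleton too short to define a curve")
    path = _longest_path(voxels)
    if len(path) < 0.5 * len(voxels):
        raise TopologyError(
            f"no dominant skeleton path: longest path covers {len(path)} of "
            f"{len(voxels)} voxels (< 50%)"
        )
    if len(path) < 8:
        raise TopologyError(
            f"skeleton path of {len(path)} voxels is too short for a spline"
        )
    pts_vox = voxels[path].astype(float)
    world = trimesh.transformations.transform_points(pts_vox, vg.transform)
    # cubic smoothing spline; smoothing relaxed until the curve stays within
    # max_spline_deviation of the skeleton voxels
    chord = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(world, axis=0), axis=1))]
    )
    u = chord / chord[-1]
    smooth = len(world) * (2.0 * voxel_pitch) ** 2
    for _ in range(12):
        tck, _ = interpolate.splprep(world.T, u=u, s=smooth, k=3)
        fitted = np.column_stack(interpolate.splev(u, tck))
        dev = np.linalg.norm(fitted - world, axis=1).max()
        if dev <= max_spline_deviation:
            break
        smooth /= 4.0
    # densify, extend the eroded ends to the canal surface, re-parameterize
    uu = np.linspace(0.0, 1.0, max(64, 4 * len(world)))
    dense = np.column_stack(interpolate.splev(uu, tck))
    dense = _extend_to_surface(dense, canal)
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    s_dense = np.concatenate([[0.0], np.cumsum(seg)])
    n_out = max(8, int(np.ceil(s_dense[-1] / resample_step)) + 1)
    s_out = np.linspace(0.0, s_dense[-1], n_out)
    points = np.column_stack(
        [np.interp(s_out, s_dense, dense[:, c]) for c in range(3)]
    )
    tangents = np.gradient(points, s_out, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True) + 1e-12
    # recompute arc length on the resampled polyline
    s_final = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(points, axis=0), axis=1))]
    )
    return Centreline(points=points, s=s_final, tangents=tangents)


def locate_targets(
    centreline: Centreline,
    nerve_target,
    fenestration_offset: float = 2.0,
) -> CanalTargets:
    """Place the electrode target and fenestration site on the centreline.

    The electrode target is the centreline point closest to the annotated
    nerve-stimulation target.  The fenestration site lies
    ``fenestration_offset`` mm along the centreline in the direction away
    from the ampullary end (the end nearer the nerve target); its tangent
    is oriented from the fenestration site toward the electrode target.
    """
    nerve_target = np.asarray(nerve_target, dtype=float)
    if fenestration_offset < 0:
        raise RangeError("fenestration offset must be >= 0")
    if fenestration_offset >= centreline.length:
        raise RangeError(
            f"fenestration offset {fenestration_offset} mm exceeds the canal "
            f"arc length {centreline.length:.2f} mm"
        )
    d = np.linalg.norm(centreline.points - nerve_target, axis=1)
    i_e = int(d.argmin())
    s_e = float(centreline.s[i_e])
    # ampullary end: the centreline end nearer the nerve stimulation target
    d_start = np.linalg.norm(centreline.points[0] - nerve_target)
    d_end = np.linalg.norm(centreline.points[-1] - nerve_target)
    away = 1.0 if d_start <= d_end else -1.0  # direction away from ampulla
    s_f = s_e + away * fenestration_offset
    if not 0.0 <= s_f <= centreline.length:
        raise RangeError(
            f"fenestration site at arc length {s_f:.2f} mm falls outside the "
            f"canal (length {centreline.length:.2f} mm)"
        )
    fen = centreline.point_at(s_f)
    tangent = centreline.tangent_at(s_f)
    if fenestration_offset > 0:
        tangent = tangent * (1.0 if s_e > s_f else -1.0)
    else:
        tangent = tangent * (-away)
    return CanalTargets(
        electrode_target=centreline.points[i_e].copy(),
        fenestration_site=fen,
        tangent=tangent,
        offset=fenestration_offset,
    )
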