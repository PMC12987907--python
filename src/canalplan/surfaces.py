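"""Derived surfaces: ROI crop, outer mastoid surface, lateral skull base,
sigmoid-sinus bounding surface and the drill entry-point region.

The segmented temporal bone is a surface "soup" that includes interior
cavity walls (air cells, the sigmoid channel).  The analysis needs several
derived surfaces:

* a cropped region of interest (vertical triangular prism);
* an *outer* surface that excludes interior cavities, obtained by
  shrink-wrapping the convex hull onto the bone (iterated uniform
  relaxation + projection);
* the lateral skull base: the connected face component superior to the
  inner-ear centre;
* a bounding surface of the sigmoid sinus, reconstructed by casting rays
  from the sinus centreline and taking the alpha shape of the hits;
* the retroauricular drill entry region: a 30 x 30 mm sagittal square with
  a 10 x 10 mm superoanterior extension, sampled with evenly spaced points
  projected laterally onto the outer surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from .anatomy import AnatomyCase, mirror_case
from .errors import ConvergenceError, CoverageError, GeometryError
from .geometry import (
    MeshDistance,
    alpha_shape,
    fibonacci_sphere,
    points_in_mesh,
    ray_mesh,
    resample_polyline,
)

__all__ = [
    "EntryRegion",
    "crop_roi",
    "extract_outer_surface",
    "extract_skull_base",
    "build_sigmoid_surface",
    "subtract_mesh",
    "build_entry_region",
    "normalize_side",
]


def crop_roi(
    temporal_bone: trimesh.Trimesh,
    inner_ear_centre,
    circumradius: float = 60.0,
    posterior_offset: float = 10.0,
) -> trimesh.Trimesh:
    """Crop the bone to a vertical triangular prism around the region of
    interest.

    The prism has an equilateral triangular footprint (circumradius
    ``circumradius`` mm) in the axial plane, centred ``posterior_offset``
    mm posterior to the inner-ear centre, and is unbounded vertically.
    Faces are kept when all three vertices satisfy the three half-plane
    inequalities.
    """
    centre = np.asarray(inner_ear_centre, dtype=float)
    if len(temporal_bone.faces) == 0:
        raise GeometryError("cannot crop an empty mesh")
    bmin, bmax = temporal_bone.bounds
    if np.any(centre < bmin - 1e-9) or np.any(centre > bmax + 1e-9):
        raise GeometryError("inner-ear centre lies outside the mesh bounding box")
    apex = centre[:2] + np.array([0.0, -posterior_offset])
    # three inward half-plane normals of an equilateral triangle (one vertex
    # pointing anterior)
    angles = np.radians([90.0, 210.0, 330.0])
    verts2d = apex + circumradius * np.column_stack([np.cos(angles), np.sin(angles)])
    inradius_normals = []
    for i in range(3):
        a, b = verts2d[i], verts2d[(i + 1) % 3]
        edge = b - a
        n = np.array([-edge[1], edge[0]])
        n /= np.linalg.norm(n)
        if np.dot(apex - a, n) < 0:
            n = -n
        inradius_normals.append((a, n))
    v2 = temporal_bone.vertices.view(np.ndarray)[:, :2]
    inside = np.ones(len(v2), dtype=bool)
    for a, n in inradius_normals:
        inside &= (v2 - a) @ n >= -1e-9
    face_ok = inside[temporal_bone.faces].all(axis=1)
    if not np.any(face_ok):
        raise GeometryError("ROI prism does not intersect the mesh")
    out = temporal_bone.submesh([np.flatnonzero(face_ok)], append=True)
    return out


def extract_outer_surface(
    temporal_bone: trimesh.Trimesh,
    target_face_area: float = 0.1,
    tol: float = 0.01,
    max_iter: int = 50,
    relax: float = 0.4,
) -> trimesh.Trimesh:
    """Shrink-wrap the convex hull onto the bone to get the outer surface.

    The convex hull is remeshed to uniformly spaced vertices (subdivision
    to the edge length of an equilateral triangle of ``target_face_area``),
    then iteratively relaxed (uniform Laplacian, tangentially dominated)
    and projected to the nearest point of the original surface until the
    maximum vertex displacement per iteration falls below ``tol`` mm.
    Because the wrap approaches from outside, interior cavity walls (air
    cells, sinus channel) are never reached.
    """
    if len(temporal_bone.faces) == 0:
        raise GeometryError("cannot wrap an empty mesh")
    hull = temporal_bone.convex_hull
    # subdivision halves edges repeatedly, leaving areas in (A/4, A]; aim
    # the cut at 2x the target so the median lands near the target itself
    edge = float(np.sqrt(8.0 * target_face_area / np.sqrt(3.0)))
    current = hull.subdivide_to_size(edge, max_iter=16)
    # displacement tolerance tracks the linear vertex spacing
    tol = max(tol, 0.03 * edge)
    md = MeshDistance(temporal_bone)
    # neighbour structure for uniform Laplacian relaxation
    n_v = len(current.vertices)
    e = current.edges_unique
    neighbors_flat = np.concatenate([e[:, 1], e[:, 0]])
    owners = np.concatenate([e[:, 0], e[:, 1]])
    degree = np.bincount(owners, minlength=n_v).astype(float)
    degree[degree == 0] = 1.0
    verts = current.vertices.view(np.ndarray).copy()
    # initial projection counts as the first iteration
    _, verts, _ = md.closest(verts)
    last = np.inf
    for it in range(max_iter):
        mean = np.zeros_like(verts)
        np.add.at(mean, owners, verts[neighbors_flat])
        mean /= degree[:, None]
        # damp the relaxation once the wrap has had time to equalize, so
        # tangential sliding along flat regions settles below tolerance
        w = relax * (0.85 ** max(0, it - 15))
        relaxed = verts + w * (mean - verts)
        _, projected, _ = md.closest(relaxed)
        disp = np.linalg.norm(projected - verts, axis=1).max()
        verts = projected
        last = disp
        if disp < tol:
            out = trimesh.Trimesh(vertices=verts, faces=current.faces, process=False)
            return out
    raise ConvergenceError(
        f"outer-surface wrap did not converge within {max_iter} iterations "
        f"(last max displacement {last:.4f} mm)",
        last_residual=float(last),
    )


def extract_skull_base(
    temporal_bone: trimesh.Trimesh,
    inner_ear_centre,
    roi_box=None,
    clip_depth: float = 3.0,
    min_up_normal: float = 0.1,
) -> trimesh.Trimesh:
    """Select the lateral-skull-base surface: the connected face component
    seeded from the face directly superior to the inner-ear centre,
    clipped to ``roi_box`` ((min, max) corners).

    When ``roi_box`` is None, a box spanning the mesh laterally and from
    ``clip_depth`` mm below the superior hit upward is used.  Growth is
    restricted to upward-facing faces (normal z > ``min_up_normal``) so
    the component cannot leak down vertical walls that share the box.
    """
    centre = np.asarray(inner_ear_centre, dtype=float)
    up = np.array([[0.0, 0.0, 1.0]])
    origin = centre.copy()
    seed_face = -1
    # walk superior hits until one faces upward (the centre may sit below
    # a plate whose first intersection is its underside)
    for _ in range(8):
        t, tri = ray_mesh(origin[None], up, temporal_bone)
        if tri[0] < 0:
            break
        origin = origin + (float(t[0]) + 1e-6) * up[0]
        if temporal_bone.face_normals[tri[0], 2] > min_up_normal:
            seed_face = int(tri[0])
            break
    if seed_face < 0:
        raise GeometryError("no face found superior to the inner-ear centre")
    hit_z = float(origin[2])
    if roi_box is None:
        bmin, bmax = temporal_bone.bounds
        roi_box = (
            np.array([bmin[0], bmin[1], hit_z - clip_depth]),
            np.array([bmax[0], bmax[1], bmax[2] + 1.0]),
        )
    lo, hi = (np.asarray(b, dtype=float) for b in roi_box)
    centroids = temporal_bone.triangles_center
    in_box = np.all((centroids >= lo) & (centroids <= hi), axis=1)
    in_box &= temporal_bone.face_normals[:, 2] > min_up_normal
    if not in_box[seed_face]:
        raise GeometryError("seed face lies outside the ROI box")
    # connected components restricted to in-box faces
    keep = np.flatnonzero(in_box)
    remap = -np.ones(len(centroids), dtype=int)
    remap[keep] = np.arange(len(keep))
    adj = temporal_bone.face_adjacency
    mask = in_box[adj].all(axis=1)
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    pairs = remap[adj[mask]]
    n = len(keep)
    graph = sp.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    component = labels == labels[remap[seed_face]]
    return temporal_bone.submesh([keep[component]], append=True)


def build_sigmoid_surface(
    sinus_centreline,
    temporal_bone: trimesh.Trimesh,
    alpha: float = 0.1,
    n_directions: int = 256,
    sample_spacing: float = 0.5,
    max_ray_length: float = 25.0,
) -> trimesh.Trimesh:
    """Reconstruct the bounding surface of the sigmoid sinus.

    Rays are cast from uniformly spaced centreline samples in uniformly
    distributed directions (Fibonacci sphere); the alpha shape
    (alpha = 0.1, circumradius threshold 1/alpha) of the hit points is
    returned.  Hits beyond ``max_ray_length`` are treated as misses so a
    sparse far wall cannot distort the shape.
    """
    centreline = np.asarray(sinus_centreline, dtype=float)
    if centreline.ndim != 2 or len(centreline) < 2:
        raise GeometryError("sinus centreline needs at least 2 points")
    samples = resample_polyline(centreline, sample_spacing)
    # keep sample points strictly interior to the sinus: endpoints of an
    # annotated centreline often sit at the segmentation boundary
    if len(samples) > 4:
        samples = samples[1:-1]
    dirs = fibonacci_sphere(n_directions)
    origins = np.repeat(samples, len(dirs), axis=0)
    directions = np.tile(dirs, (len(samples), 1))
    # rays are capped at max_ray_length, so only faces within reach matter
    lo = samples.min(axis=0) - max_ray_length
    hi = samples.max(axis=0) + max_ray_length
    cent = temporal_bone.triangles_center
    sel = np.flatnonzero(np.all((cent >= lo) & (cent <= hi), axis=1))
    target = (
        temporal_bone.submesh([sel], append=True)
        if 0 < len(sel) < len(cent)
        else temporal_bone
    )
    t, tri = ray_mesh(origins, directions, target)
    ok = np.isfinite(t) & (t <= max_ray_length)
    hits = origins[ok] + t[ok, None] * directions[ok]
    if len(hits) < 4:
        raise GeometryError("fewer than 4 sigmoid ray hits; cannot build surface")
    return alpha_shape(hits, alpha)


def subtract_mesh(
    surface: trimesh.Trimesh, cutter: trimesh.Trimesh
) -> trimesh.Trimesh:
    """Remove the faces of ``surface`` whose centroids lie inside the closed
    ``cutter`` surface (containment-based subtraction)."""
    inside = points_in_mesh(surface.triangles_center, cutter)
    keep = np.flatnonzero(~inside)
    if len(keep) == 0:
        raise GeometryError("subtraction removed every face")
    if len(keep) == len(surface.faces):
        return surface
    return surface.submesh([keep], append=True)


@dataclass
class EntryRegion:
    """Drill entry-point region on the outer mastoid surface.

    The planar domain is a 30 x 30 mm sagittal square whose anterior edge
    is at the ear-canal centre's anteroposterior coordinate, vertically
    centred on the ear canal, plus a 10 x 10 mm superoanterior extension
    toward the zygomatic process.  (u, v) planar coordinates: u = mm
    posterior of the anterior edge (the extension has u < 0), v = mm
    superior of the vertical centre.
    """

    points: np.ndarray  # (n, 3) on the outer surface
    normals: np.ndarray  # (n, 3) outward surface normals
    uv: np.ndarray  # (n, 2)
    eac_centre: np.ndarray  # (3,)
    square: float = 30.0
    extension: float = 10.0

    def __len__(self):
        return len(self.points)

    @property
    def planar_area(self) -> float:
        return self.square**2 + self.extension**2

    def contains_uv(self, uv) -> np.ndarray:
        uv = np.atleast_2d(uv)
        u, v = uv[:, 0], uv[:, 1]
        h = self.square / 2.0
        in_square = (u >= 0) & (u <= self.square) & (np.abs(v) <= h)
        in_ext = (
            (u >= -self.extension) & (u <= 0) & (v >= h - self.extension) & (v <= h)
        )
        return in_square | in_ext

    def to_json(self, path) -> None:
        payload = {
            "eac_centre": self.eac_centre.tolist(),
            "square": self.square,
            "extension": self.extension,
            "points": self.points.tolist(),
            "normals": self.normals.tolist(),
            "uv": self.uv.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "EntryRegion":
        d = json.loads(Path(path).read_text())
        return cls(
            points=np.asarray(d["points"], dtype=float),
            normals=np.asarray(d["normals"], dtype=float),
            uv=np.asarray(d["uv"], dtype=float),
            eac_centre=np.asarray(d["eac_centre"], dtype=float),
            square=d["square"],
            extension=d["extension"],
        )


def _domain_samples(n_points, square, extension, seed, jitter):
    """Stratified jittered grid with exactly ``n_points`` samples inside the
    planar domain, deterministically from ``seed``."""
    area = square**2 + extension**2
    rng = np.random.default_rng(seed)
    h = square / 2.0

    def inside(u, v):
        in_sq = (u >= 0) & (u <= square) & (np.abs(v) <= h)
        in_ext = (u >= -extension) & (u <= 0) & (v >= h - extension) & (v <= h)
        return in_sq | in_ext

    def grid(n_cells):
        cell = np.sqrt(area / n_cells)
        uu = np.arange(-extension + cell / 2.0, square, cell)
        vv = np.arange(-h + cell / 2.0, h, cell)
        U, V = np.meshgrid(uu, vv, indexing="ij")
        ok = inside(U.ravel(), V.ravel())
        return np.column_stack([U.ravel()[ok], V.ravel()[ok]]), cell

    # bisect the cell count to the smallest grid holding >= n_points samples
    lo_cells, hi_cells = n_points, 4 * n_points
    best = None
    while lo_cells <= hi_cells:
        n_cells = (lo_cells + hi_cells) // 2
        centres, cell = grid(n_cells)
        if len(centres) >= n_points:
            best = (centres, cell)
            hi_cells = n_cells - 1
        else:
            lo_cells = n_cells + 1
    if best is None:
        best = grid(4 * n_points)
    centres, cell = best
    # drop surplus cells with an even stride to keep spacing uniform
    surplus = len(centres) - n_points
    if surplus > 0:
        drop = np.linspace(0, len(centres) - 1, surplus).astype(int)
        keep = np.ones(len(centres), dtype=bool)
        keep[drop] = False
        centres = centres[keep]
    offsets = rng.uniform(-jitter * cell, jitter * cell, size=centres.shape)
    uv = centres + offsets
    # jitter must not push a sample outside the domain
    bad = ~inside(uv[:, 0], uv[:, 1])
    uv[bad] = centres[bad]
    return uv, cell


def build_entry_region(
    outer_surface: trimesh.Trimesh,
    eac_centre,
    n_points: int = 5000,
    square: float = 30.0,
    extension: float = 10.0,
    seed: int = 0,
    jitter: float = 0.25,
    max_miss_fraction: float = 0.01,
) -> EntryRegion:
    """Sample the drill entry-point region and project it laterally (-x)
    onto the outer surface.

    Raises :class:`CoverageError` when more than ``max_miss_fraction`` of
    the planar samples fail to hit the surface.
    """
    eac_centre = np.asarray(eac_centre, dtype=float)
    uv, cell = _domain_samples(n_points, square, extension, seed, jitter)
    # u posterior of the anterior edge, v superior of the vertical centre
    y = eac_centre[1] - uv[:, 0]
    z = eac_centre[2] + uv[:, 1]
    x_start = outer_surface.bounds[1][0] + 5.0
    origins = np.column_stack([np.full(len(uv), x_start), y, z])
    directions = np.tile([-1.0, 0.0, 0.0], (len(uv), 1))
    t, tri = ray_mesh(origins, directions, outer_surface)
    miss = ~np.isfinite(t)
    if miss.mean() > max_miss_fraction:
        raise CoverageError(
            f"{miss.sum()} of {len(uv)} entry samples miss the outer surface "
            f"({100 * miss.mean():.1f}% > {100 * max_miss_fraction:.0f}%)"
        )
    if np.any(miss):
        # re-jitter missed samples inside their cells until they hit
        rng = np.random.default_rng(seed + 1)
        for i in np.flatnonzero(miss):
            for _ in range(20):
                trial = uv[i] + rng.uniform(-0.5 * cell, 0.5 * cell, size=2)
                o = np.array(
                    [[x_start, eac_centre[1] - trial[0], eac_centre[2] + trial[1]]]
                )
                th, trih = ray_mesh(o, directions[:1], outer_surface)
                if np.isfinite(th[0]):
                    uv[i] = trial
                    t[i], tri[i] = th[0], trih[0]
                    origins[i] = o[0]
                    break
            else:
                raise CoverageError("could not recover a missed entry sample")
    points = origins + t[:, None] * directions
    normals = outer_surface.face_normals[tri]
    return EntryRegion(
        points=points,
        normals=normals,
        uv=uv,
        eac_centre=eac_centre,
        square=square,
        extension=extension,
    )


def normalize_side(case: AnatomyCase) -> AnatomyCase:
    """Bring a case into the right-ear convention: left cases are mirrored
    about the sagittal plane through the inner-ear centre (winding flipped
    so outward normals are preserved); right cases are returned unchanged."""
    if case.side == "right":
        return case
    mirrored = mirror_case(case)
    mirrored.side = "right"
    return mirrored
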