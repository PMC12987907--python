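"""Vectorized geometric primitives shared across the pipeline.

This module provides the low-level queries every stage relies on:

* exact closest-point / signed-distance queries against triangle meshes
  (:class:`MeshDistance`), using a k-d tree over triangle centroids with a
  guaranteed-correct refinement pass and angle-weighted pseudonormals for
  the inside/outside sign;
* a chunked Möller–Trumbore ray caster (:func:`ray_mesh`);
* tube meshing along arbitrary curves (:func:`tube_along_curve`);
* a 3-D alpha shape built on the Delaunay tetrahedralization
  (:func:`alpha_shape`);
* small helpers (Fibonacci sphere directions, minimal enclosing circle of
  three points, mesh mirroring, polyline resampling).

All coordinates are in millimetres.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy.spatial import Delaunay, cKDTree

from .errors import GeometryError

try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is expected to be present
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f

        return deco


@_njit(cache=False, fastmath=True)
def _closest_block_kernel(points, cand, cand_dc, centre, r_max, tris):
    """Closest point over one shared, centroid-distance-sorted candidate
    list (used for grid blocks).

    For a node p and candidate t, dist(p, t) >= cand_dc[t] - dist(p,
    centre) - r_max; once that lower bound exceeds the incumbent the
    remaining (sorted) candidates cannot win and the scan stops.
    """
    n = points.shape[0]
    m = cand.shape[0]
    out_d = np.empty(n)
    out_p = np.empty((n, 3))
    out_t = np.empty(n, np.int64)
    for i in range(n):
        px, py, pz = points[i, 0], points[i, 1], points[i, 2]
        dxc = px - centre[0]
        dyc = py - centre[1]
        dzc = pz - centre[2]
        d_pc = np.sqrt(dxc * dxc + dyc * dyc + dzc * dzc)
        bd = 1e300
        bx = by = bz = 0.0
        bt = -1
        for j in range(m):
            lb = cand_dc[j] - d_pc - r_max
            if lb > 0.0 and lb * lb > bd:
                break
            t = cand[j]
            qx, qy, qz = _closest_point_on_triangle(px, py, pz, tris, t)
            ddx, ddy, ddz = px - qx, py - qy, pz - qz
            dd = ddx * ddx + ddy * ddy + ddz * ddz
            if dd < bd:
                bd = dd
                bx, by, bz = qx, qy, qz
                bt = t
        out_d[i] = np.sqrt(bd)
        out_p[i, 0], out_p[i, 1], out_p[i, 2] = bx, by, bz
        out_t[i] = bt
    return out_d, out_p, out_t


@_njit(cache=False, fastmath=True, inline="always")
def _closest_point_on_triangle(px, py, pz, tris, t):
    ax, ay, az = tris[t, 0, 0], tris[t, 0, 1], tris[t, 0, 2]
    bx_, by_, bz_ = tris[t, 1, 0], tris[t, 1, 1], tris[t, 1, 2]
    cx, cy, cz = tris[t, 2, 0], tris[t, 2, 1], tris[t, 2, 2]
    abx, aby, abz = bx_ - ax, by_ - ay, bz_ - az
    acx, acy, acz = cx - ax, cy - ay, cz - az
    apx, apy, apz = px - ax, py - ay, pz - az
    d1 = abx * apx + aby * apy + abz * apz
    d2 = acx * apx + acy * apy + acz * apz
    if d1 <= 0.0 and d2 <= 0.0:
        return ax, ay, az
    bpx, bpy, bpz = px - bx_, py - by_, pz - bz_
    d3 = abx * bpx + aby * bpy + abz * bpz
    d4 = acx * bpx + acy * bpy + acz * bpz
    if d3 >= 0.0 and d4 <= d3:
        return bx_, by_, bz_
    vc = d1 * d4 - d3 * d2
    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
        w = d1 / (d1 - d3)
        return ax + w * abx, ay + w * aby, az + w * abz
    cpx, cpy, cpz = px - cx, py - cy, pz - cz
    d5 = abx * cpx + aby * cpy + abz * cpz
    d6 = acx * cpx + acy * cpy + acz * cpz
    if d6 >= 0.0 and d5 <= d6:
        return cx, cy, cz
    vb = d5 * d2 - d1 * d6
    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
        w = d2 / (d2 - d6)
        return ax + w * acx, ay + w * acy, az + w * acz
    va = d3 * d6 - d5 * d4
    if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return bx_ + w * (cx - bx_), by_ + w * (cy - by_), bz_ + w * (cz - bz_)
    denom = 1.0 / (va + vb + vc)
    v = vb * denom
    w = vc * denom
    return ax + abx * v + acx * w, ay + aby * v + acy * w, az + abz * v + acz * w


@_njit(cache=False, fastmath=True)
def _closest_on_candidates_kernel(points, idx, tris):
    """Closest point over candidate triangles per query point.

    Scalar Ericson closest-point-on-triangle in a tight loop; returns
    (distance, closest point, winning triangle index) per point.
    """
    n, k = idx.shape
    out_d = np.empty(n)
    out_p = np.empty((n, 3))
    out_t = np.empty(n, np.int64)
    for i in range(n):
        px, py, pz = points[i, 0], points[i, 1], points[i, 2]
        bd = 1e300
        bx = by = bz = 0.0
        bt = -1
        for j in range(k):
            t = idx[i, j]
            ax, ay, az = tris[t, 0, 0], tris[t, 0, 1], tris[t, 0, 2]
            bx_, by_, bz_ = tris[t, 1, 0], tris[t, 1, 1], tris[t, 1, 2]
            cx, cy, cz = tris[t, 2, 0], tris[t, 2, 1], tris[t, 2, 2]
            abx, aby, abz = bx_ - ax, by_ - ay, bz_ - az
            acx, acy, acz = cx - ax, cy - ay, cz - az
            apx, apy, apz = px - ax, py - ay, pz - az
            d1 = abx * apx + aby * apy + abz * apz
            d2 = acx * apx + acy * apy + acz * apz
            if d1 <= 0.0 and d2 <= 0.0:
                qx, qy, qz = ax, ay, az
            else:
                bpx, bpy, bpz = px - bx_, py - by_, pz - bz_
                d3 = abx * bpx + aby * bpy + abz * bpz
                d4 = acx * bpx + acy * bpy + acz * bpz
                if d3 >= 0.0 and d4 <= d3:
                    qx, qy, qz = bx_, by_, bz_
                else:
                    vc = d1 * d4 - d3 * d2
                    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
                        w = d1 / (d1 - d3)
                        qx, qy, qz = ax + w * abx, ay + w * aby, az + w * abz
                    else:
                        cpx, cpy, cpz = px - cx, py - cy, pz - cz
                        d5 = abx * cpx + aby * cpy + abz * cpz
                        d6 = acx * cpx + acy * cpy + acz * cpz
                        if d6 >= 0.0 and d5 <= d6:
                            qx, qy, qz = cx, cy, cz
                        else:
                            vb = d5 * d2 - d1 * d6
                            if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
                                w = d2 / (d2 - d6)
                                qx, qy, qz = (
                                    ax + w * acx,
                                    ay + w * acy,
                                    az + w * acz,
                                )
                            else:
                                va = d3 * d6 - d5 * d4
                                if (
                                    va <= 0.0
                                    and (d4 - d3) >= 0.0
                                    and (d5 - d6) >= 0.0
                                ):
                                    w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
                                    qx = bx_ + w * (cx - bx_)
                                    qy = by_ + w * (cy - by_)
                                    qz = bz_ + w * (cz - bz_)
                                else:
                                    denom = 1.0 / (va + vb + vc)
                                    v = vb * denom
                                    w = vc * denom
                                    qx = ax + abx * v + acx * w
                                    qy = ay + aby * v + acy * w
                                    qz = az + abz * v + acz * w
            dx, dy, dz = px - qx, py - qy, pz - qz
            dd = dx * dx + dy * dy + dz * dz
            if dd < bd:
                bd = dd
                bx, by, bz = qx, qy, qz
                bt = t
        out_d[i] = np.sqrt(bd)
        out_p[i, 0], out_p[i, 1], out_p[i, 2] = bx, by, bz
        out_t[i] = bt
    return out_d, out_p, out_t

__all__ = [
    "MeshDistance",
    "ray_mesh",
    "points_in_mesh",
    "tube_along_curve",
    "alpha_shape",
    "fibonacci_sphere",
    "min_enclosing_circle_3pts",
    "mirror_mesh",
    "resample_polyline",
]

_EPS = 1e-12


def fibonacci_sphere(n: int) -> np.ndarray:
    """Return ``n`` near-uniformly distributed unit vectors (Fibonacci lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


class MeshDistance:
    """Exact closest-point and signed-distance queries against a triangle mesh.

    Candidate triangles are found with a k-d tree over triangle centroids;
    a refinement pass re-queries any point whose current best distance could
    still be beaten by a triangle outside the candidate set, so returned
    distances are exact (to floating point) rather than approximate.

    The sign is assigned with angle-weighted pseudonormals (Bærentzen &
    Aanæs), which is exact for watertight meshes: negative inside, positive
    outside.  For non-watertight meshes only unsigned distances are
    meaningful and :meth:`signed_distance` falls back to unsigned values.
    """

    def __init__(self, mesh: trimesh.Trimesh):
        if len(mesh.faces) == 0:
            raise GeometryError("cannot build distance structure for an empty mesh")
        self.mesh = mesh
        self.triangles = mesh.triangles.view(np.ndarray)
        self._tris_c = np.ascontiguousarray(self.triangles)
        self.centroids = self.triangles.mean(axis=1)
        # radius of the bounding sphere of each triangle about its centroid
        self._tri_radius = np.linalg.norm(
            self.triangles - self.centroids[:, None, :], axis=2
        ).max(axis=1)
        self._r_max = float(self._tri_radius.max())
        self.tree = cKDTree(self.centroids)
        self.watertight = bool(mesh.is_watertight)
        self._pseudo = None  # built lazily

    # -- closest point ---------------------------------------------------

    def closest(self, points, k: int = 8):
        """Return ``(distance, closest_point, triangle_index)`` for each point.

        Exactness certificate: any triangle outside the examined candidate
        set has centroid distance >= d_cent_k, hence surface distance
        >= d_cent_k - r_max.  Points whose current best does not beat that
        bound are re-queried with an escalating candidate count until the
        certificate holds (or all triangles have been examined).
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if len(points) > 32768:
            parts = [
                self.closest(points[s : s + 32768], k=k)
                for s in range(0, len(points), 32768)
            ]
            return tuple(np.concatenate([p[i] for p in parts]) for i in range(3))
        n_tri = len(self.triangles)
        k = min(k, n_tri)
        d_cent, idx = self.tree.query(points, k=k)
        if k == 1:
            d_cent = d_cent[:, None]
            idx = idx[:, None]
        best_d, best_p, best_t = self._min_over_candidates(points, idx)
        need = best_d > d_cent[:, -1] - self._r_max if k < n_tri else None
        while need is not None and np.any(need):
            k = min(k * 8, n_tri)
            sub = np.flatnonzero(need)
            d_cent_s, idx_s = self.tree.query(points[sub], k=k)
            if k == 1:
                d_cent_s, idx_s = d_cent_s[:, None], idx_s[:, None]
            # only candidates that could beat the incumbent need evaluation;
            # compact the keepers leftward, padding with candidate 0
            keep = d_cent_s < (best_d[sub, None] + self._r_max + 1e-9)
            keep[:, 0] = True
            order = np.argsort(~keep, axis=1, kind="stable")
            idx_sorted = np.take_along_axis(idx_s, order, axis=1)
            mcand = int(keep.sum(axis=1).max())
            pad = np.where(
                np.take_along_axis(keep, order, axis=1)[:, :mcand],
                idx_sorted[:, :mcand],
                idx_sorted[:, :1],
            )
            d, p, t = self._min_over_candidates(points[sub], pad)
            better = d < best_d[sub]
            rows = sub[better]
            best_d[rows], best_p[rows], best_t[rows] = d[better], p[better], t[better]
            if k >= n_tri:
                break
            need[sub] = best_d[sub] > d_cent_s[:, -1] - self._r_max
        return best_d, best_p, best_t

    def _min_over_candidates(self, points, idx, max_pairs: int = 2_000_000):
        npts, k = idx.shape
        if _HAVE_NUMBA:
            return _closest_on_candidates_kernel(
                np.ascontiguousarray(points),
                np.ascontiguousarray(idx.astype(np.int64)),
                self._tris_c,
            )
        out_d = np.empty(npts)
        out_p = np.empty((npts, 3))
        out_t = np.empty(npts, dtype=idx.dtype)
        block = max(1, max_pairs // max(k, 1))
        for s in range(0, npts, block):
            sl = slice(s, min(s + block, npts))
            idx_b = idx[sl]
            nb = idx_b.shape[0]
            flat_tris = self.triangles[idx_b.ravel()]
            flat_pts = np.repeat(points[sl], k, axis=0)
            cp = trimesh.triangles.closest_point(flat_tris, flat_pts)
            d = np.linalg.norm(cp - flat_pts, axis=1).reshape(nb, k)
            j = d.argmin(axis=1)
            rows = np.arange(nb)
            out_d[sl] = d[rows, j]
            out_p[sl] = cp.reshape(nb, k, 3)[rows, j]
            out_t[sl] = idx_b[rows, j]
        return out_d, out_p, out_t

    def grid_closest(self, origin, spacing: float, shape, block: int = 8):
        """Exact closest-point query on a regular grid, evaluated per node
        block.

        For each block of nodes one vectorized centroid cull yields a
        candidate triangle set that provably contains every node's nearest
        triangle: with u = (min centroid distance from the block centre)
        + r_max an upper bound on the centre's surface distance, any
        winner for a node within half-diagonal h of the centre has
        centroid distance at most u + 2h + r_max from the centre.
        Returns (distance, closest point, triangle index) as flat arrays
        in C (ij) node order.
        """
        origin = np.asarray(origin, dtype=float)
        shape = tuple(int(n) for n in shape)
        n_total = int(np.prod(shape))
        out_d = np.empty(n_total)
        out_p = np.empty((n_total, 3))
        out_t = np.empty(n_total, dtype=np.int64)
        axes = [origin[i] + spacing * np.arange(shape[i]) for i in range(3)]
        flat = np.arange(n_total).reshape(shape)
        cents = self.centroids
        for i0 in range(0, shape[0], block):
            for j0 in range(0, shape[1], block):
                for k0 in range(0, shape[2], block):
                    i1 = min(i0 + block, shape[0])
                    j1 = min(j0 + block, shape[1])
                    k1 = min(k0 + block, shape[2])
                    ax, ay, az = axes[0][i0:i1], axes[1][j0:j1], axes[2][k0:k1]
                    lo = np.array([ax[0], ay[0], az[0]])
                    hi = np.array([ax[-1], ay[-1], az[-1]])
                    centre = (lo + hi) / 2.0
                    halfdiag = float(np.linalg.norm(hi - lo) / 2.0)
                    dc = np.linalg.norm(cents - centre, axis=1)
                    u = dc.min() + self._r_max
                    cand = np.flatnonzero(
                        dc <= u + 2.0 * halfdiag + self._r_max + 1e-9
                    ).astype(np.int64)
                    cand = cand[np.argsort(dc[cand], kind="stable")]
                    X, Y, Z = np.meshgrid(ax, ay, az, indexing="ij")
                    pts = np.ascontiguousarray(
                        np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
                    )
                    if _HAVE_NUMBA:
                        d, p, t = _closest_block_kernel(
                            pts,
                            cand,
                            np.ascontiguousarray(dc[cand]),
                            centre,
                            self._r_max,
                            self._tris_c,
                        )
                    else:  # pragma: no cover - exercised only without numba
                        d, p, t = self._min_over_candidates(
                            pts, np.tile(cand, (len(pts), 1))
                        )
                    idx = flat[i0:i1, j0:j1, k0:k1].ravel()
                    out_d[idx] = d
                    out_p[idx] = p
                    out_t[idx] = t
        return out_d, out_p, out_t

    def grid_signed_distance(self, origin, spacing: float, shape, block: int = 8):
        """Signed variant of :meth:`grid_closest` (flat C-order values)."""
        origin = np.asarray(origin, dtype=float)
        d, cp, ti = self.grid_closest(origin, spacing, shape, block=block)
        if not self.watertight:
            return d
        axes = [origin[i] + spacing * np.arange(shape[i]) for i in range(3)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        return self._apply_sign(pts, d, cp, ti)

    # -- sign ------------------------------------------------------------

    def _build_pseudonormals(self):
        mesh = self.mesh
        fn = mesh.face_normals.view(np.ndarray)
        tri = self.triangles
        # angle-weighted vertex pseudonormals
        vn = np.zeros_like(mesh.vertices, dtype=float)
        for c in range(3):
            a = tri[:, c]
            b = tri[:, (c + 1) % 3]
            d = tri[:, (c + 2) % 3]
            u = b - a
            v = d - a
            cosang = np.einsum("ij,ij->i", u, v) / (
                np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1) + _EPS
            )
            ang = np.arccos(np.clip(cosang, -1.0, 1.0))
            np.add.at(vn, mesh.faces[:, c], ang[:, None] * fn)
        norms = np.linalg.norm(vn, axis=1)
        vn /= np.maximum(norms, _EPS)[:, None]
        # edge pseudonormals: mean of the two adjacent face normals, keyed by
        # an encoded sorted vertex pair for vectorized lookup
        nv = len(mesh.vertices)
        fa = np.asarray(mesh.face_adjacency)
        fae = np.sort(np.asarray(mesh.face_adjacency_edges), axis=1)
        en = fn[fa[:, 0]] + fn[fa[:, 1]]
        en /= np.linalg.norm(en, axis=1, keepdims=True) + _EPS
        keys = fae[:, 0].astype(np.int64) * nv + fae[:, 1]
        order = np.argsort(keys)
        self._pseudo = (fn, vn, keys[order], en[order], nv)

    def signed_distance(self, points, k: int = 8):
        """Signed distance: negative inside (watertight meshes), else unsigned."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        d, cp, ti = self.closest(points, k=k)
        if not self.watertight:
            return d
        return self._apply_sign(points, d, cp, ti)

    def _apply_sign(self, points, d, cp, ti):
        if self._pseudo is None:
            self._build_pseudonormals()
        fn, vn, edge_keys, edge_norms, nv = self._pseudo
        bary = trimesh.triangles.points_to_barycentric(self.triangles[ti], cp)
        faces = self.mesh.faces.view(np.ndarray)[ti]
        tol = 1e-6
        normals = fn[ti].copy()
        low = bary < tol
        nlow = low.sum(axis=1)
        # closest feature is a vertex (two barycentric coords ~ 0)
        at_vertex = nlow >= 2
        if np.any(at_vertex):
            vi = faces[at_vertex, np.argmax(bary[at_vertex], axis=1)]
            normals[at_vertex] = vn[vi]
        # closest feature is an edge (one coord ~ 0)
        at_edge = np.flatnonzero(nlow == 1)
        if len(at_edge):
            zero_c = np.argmin(bary[at_edge], axis=1)
            cols = np.array([[1, 2], [0, 2], [0, 1]])[zero_c]
            ev = np.take_along_axis(faces[at_edge], cols, axis=1)
            ev.sort(axis=1)
            k_query = ev[:, 0].astype(np.int64) * nv + ev[:, 1]
            pos = np.searchsorted(edge_keys, k_query)
            pos = np.clip(pos, 0, len(edge_keys) - 1)
            found = edge_keys[pos] == k_query
            normals[at_edge[found]] = edge_norms[pos[found]]
        sign = np.where(
            np.einsum("ij,ij->i", points - cp, normals) >= 0.0, 1.0, -1.0
        )
        return sign * d


def ray_mesh(
    origins,
    directions,
    mesh: trimesh.Trimesh,
    first_hit: bool = True,
    chunk_pairs: int = 8_000_000,
):
    """Chunked Möller–Trumbore ray/mesh intersection.

    Parameters
    ----------
    origins, directions : (n, 3) arrays
        Ray origins and (not necessarily unit) directions.
    first_hit : bool
        If True return the nearest hit per ray, else all hit parameters.

    Returns
    -------
    If ``first_hit``: ``(t, tri_index)`` arrays of length n; misses carry
    ``t = inf`` and ``tri_index = -1``.  Hit point is ``origin + t*direction``.
    If not ``first_hit``: list of sorted hit-parameter arrays per ray.
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    tri = mesh.triangles.view(np.ndarray)
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0
    e2 = tri[:, 2] - v0
    n_rays, n_tris = len(origins), len(tri)
    best_t = np.full(n_rays, np.inf)
    best_tri = np.full(n_rays, -1, dtype=int)
    all_hits = [[] for _ in range(n_rays)] if not first_hit else None
    rows = max(1, chunk_pairs // max(n_tris, 1))
    eps = 1e-9
    for start in range(0, n_rays, rows):
        o = origins[start : start + rows][:, None, :]
        d = directions[start : start + rows][:, None, :]
        h = np.cross(d, e2[None, :, :])
        a = np.einsum("rtk,tk->rt", h, e1)
        valid = np.abs(a) > eps
        f = np.where(valid, 1.0 / np.where(valid, a, 1.0), 0.0)
        s = o - v0[None, :, :]
        u = f * np.einsum("rtk,rtk->rt", s, h)
        q = np.cross(s, e1[None, :, :])
        v = f * np.einsum("rtk,rtk->rt", q, np.broadcast_to(d, q.shape))
        t = f * np.einsum("rtk,tk->rt", q, e2)
        hit = (
            valid
            & (u >= -eps)
            & (v >= -eps)
            & (u + v <= 1.0 + eps)
            & (t > eps)
        )
        t_masked = np.where(hit, t, np.inf)
        tmin = t_masked.min(axis=1)
        argt = t_masked.argmin(axis=1)
        sl = slice(start, start + len(tmin))
        best_t[sl] = tmin
        best_tri[sl] = np.where(np.isfinite(tmin), argt, -1)
        if all_hits is not None:
            ridx, tidx = np.nonzero(hit)
            for r, tt in zip(ridx, t[ridx, tidx]):
                all_hits[start + r].append(tt)
    if first_hit:
        return best_t, best_tri
    return [np.sort(np.asarray(h)) for h in all_hits]


def points_in_mesh(points, mesh: trimesh.Trimesh) -> np.ndarray:
    """Crossing-parity containment test (robust for closed, even non-manifold
    surfaces such as alpha-shape boundaries)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    direction = np.array([0.5773502692, 0.5257311121, 0.6234898019])
    dirs = np.tile(direction, (len(points), 1))
    hits = ray_mesh(points, dirs, mesh, first_hit=False)
    return np.array([len(h) % 2 == 1 for h in hits])


def resample_polyline(points, spacing: float) -> np.ndarray:
    """Resample an ordered polyline at (approximately) uniform arc length."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total < _EPS:
        return points[:1].copy()
    n = max(2, int(np.ceil(total / spacing)) + 1)
    si = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for c in range(3):
        out[:, c] = np.interp(si, s, points[:, c])
    return out


def tube_along_curve(
    points,
    radii,
    n_circ: int = 16,
    caps: bool = True,
) -> trimesh.Trimesh:
    """Build a watertight tube mesh around an ordered curve.

    ``radii`` may be a scalar or per-point array, allowing ampullary
    swellings.  Frames are propagated along the curve (parallel transport)
    to avoid twisting.
    """
    points = np.asarray(points, dtype=float)
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (len(points),))
    n = len(points)
    if n < 2:
        raise GeometryError("tube requires at least two curve points")
    # tangents
    tang = np.gradient(points, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True) + _EPS
    # parallel-transported frames
    normal = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(normal, tang[0])) > 0.9:
        normal = np.array([0.0, 1.0, 0.0])
    normal = normal - np.dot(normal, tang[0]) * tang[0]
    normal /= np.linalg.norm(normal)
    frames = np.empty((n, 2, 3))
    for i in range(n):
        if i > 0:
            # rotate previous normal into current tangent plane
            normal = normal - np.dot(normal, tang[i]) * tang[i]
            nrm = np.linalg.norm(normal)
            if nrm < 1e-8:
                normal = np.cross(tang[i], frames[i - 1, 1])
                nrm = np.linalg.norm(normal)
            normal = normal / nrm
        binorm = np.cross(tang[i], normal)
        binorm /= np.linalg.norm(binorm) + _EPS
        frames[i, 0] = normal
        frames[i, 1] = binorm
    ang = np.linspace(0.0, 2 * np.pi, n_circ, endpoint=False)
    ca, sa = np.cos(ang), np.sin(ang)
    verts = (
        points[:, None, :]
        + radii[:, None, None]
        * (ca[None, :, None] * frames[:, None, 0] + sa[None, :, None] * frames[:, None, 1])
    ).reshape(-1, 3)
    faces = []
    for i in range(n - 1):
        base0 = i * n_circ
        base1 = (i + 1) * n_circ
        for j in range(n_circ):
            j1 = (j + 1) % n_circ
            faces.append([base0 + j, base1 + j1, base1 + j])
            faces.append([base0 + j, base0 + j1, base1 + j1])
    verts_list = [verts]
    if caps:
        c0 = len(verts)
        verts_list.append(points[0][None])
        for j in range(n_circ):
            faces.append([c0, (j + 1) % n_circ, j])
        c1 = c0 + 1
        verts_list.append(points[-1][None])
        base = (n - 1) * n_circ
        for j in range(n_circ):
            faces.append([c1, base + j, base + (j + 1) % n_circ])
    mesh = trimesh.Trimesh(
        vertices=np.vstack(verts_list), faces=np.asarray(faces), process=False
    )
    return mesh


def alpha_shape(points, alpha: float):
    """3-D alpha shape of a point cloud.

    A tetrahedron of the Delaunay complex is kept when its circumradius is
    below ``1/alpha`` (the convention of the `alphashape` package).  Returns
    the boundary surface of the kept complex as a mesh; the exact volume of
    the kept complex is stored in ``mesh.metadata['complex_volume']``.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 4:
        raise GeometryError("alpha shape requires at least 4 points")
    try:
        dt = Delaunay(points)
    except Exception as exc:  # qhull degenerate input
        raise GeometryError(f"Delaunay triangulation failed: {exc}") from exc
    tets = dt.simplices
    p = points[tets]  # (m, 4, 3)
    a, b, c, d = p[:, 0], p[:, 1], p[:, 2], p[:, 3]
    # circumcentre from 3 plane equations 2(x-a)·(b-a) = |b|^2-|a|^2 etc.
    A = 2.0 * np.stack([b - a, c - a, d - a], axis=1)
    rhs = np.stack(
        [
            np.einsum("ij,ij->i", b, b) - np.einsum("ij,ij->i", a, a),
            np.einsum("ij,ij->i", c, c) - np.einsum("ij,ij->i", a, a),
            np.einsum("ij,ij->i", d, d) - np.einsum("ij,ij->i", a, a),
        ],
        axis=1,
    )
    det = np.linalg.det(A)
    ok = np.abs(det) > 1e-12
    centre = np.full((len(tets), 3), np.inf)
    if np.any(ok):
        centre[ok] = np.linalg.solve(A[ok], rhs[ok][..., None])[..., 0]
    radius = np.linalg.norm(centre - a, axis=1)
    keep = ok & (radius < 1.0 / alpha)
    if not np.any(keep):
        raise GeometryError("alpha shape is empty at this alpha")
    kept = tets[keep]
    # exact complex volume
    v = np.abs(
        np.einsum(
            "ij,ij->i",
            points[kept[:, 1]] - points[kept[:, 0]],
            np.cross(
                points[kept[:, 2]] - points[kept[:, 0]],
                points[kept[:, 3]] - points[kept[:, 0]],
            ),
        )
    ).sum() / 6.0
    # boundary faces: appear exactly once among kept tetrahedra; orient each
    # so its normal points away from the opposite vertex of its tetrahedron
    local = [(0, 1, 2, 3), (0, 3, 1, 2), (0, 2, 3, 1), (1, 3, 2, 0)]
    face_count: dict = {}
    for li in local:
        for tet in kept:
            f = (tet[li[0]], tet[li[1]], tet[li[2]])
            key = tuple(sorted(f))
            if key in face_count:
                face_count[key] = None
            else:
                face_count[key] = (f, tet[li[3]])
    faces = []
    for key, val in face_count.items():
        if val is None:
            continue
        (i0, i1, i2), opp = val
        nrm = np.cross(points[i1] - points[i0], points[i2] - points[i0])
        if np.dot(nrm, points[opp] - points[i0]) > 0:
            i1, i2 = i2, i1
        faces.append([i0, i1, i2])
    mesh = trimesh.Trimesh(vertices=points, faces=np.asarray(faces), process=False)
    mesh.metadata["complex_volume"] = float(v)
    return mesh


def min_enclosing_circle_3pts(p0, p1, p2) -> float:
    """Diameter of the minimal enclosing circle of three 3-D points.

    The circle lies in the plane of the points: the longest side if the
    triangle is obtuse/right, otherwise the circumcircle.
    """
    p = [np.asarray(q, dtype=float) for q in (p0, p1, p2)]
    d = np.array(
        [
            np.linalg.norm(p[1] - p[2]),
            np.linalg.norm(p[0] - p[2]),
            np.linalg.norm(p[0] - p[1]),
        ]
    )
    a, b, c = np.sort(d)[::-1]
    if a**2 >= b**2 + c**2:
        return float(a)
    area = 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
    if area < _EPS:
        return float(a)
    return float(a * b * c / (2.0 * area))


def mirror_mesh(mesh: trimesh.Trimesh, plane_x: float) -> trimesh.Trimesh:
    """Reflect a mesh about the sagittal plane x = plane_x, preserving
    outward orientation by flipping the triangle winding."""
    v = mesh.vertices.view(np.ndarray).copy()
    v[:, 0] = 2.0 * plane_x - v[:, 0]
    f = mesh.faces.view(np.ndarray)[:, ::-1].copy()
    return trimesh.Trimesh(vertices=v, faces=f, process=False)
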