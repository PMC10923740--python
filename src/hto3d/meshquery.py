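"""Spatial queries on triangle meshes: nearest surface point and ray casting.

Queries are built on a :class:`scipy.spatial.cKDTree` over triangle centroids
with an exact point-to-triangle refinement stage, so results are exact (the
candidate set is enlarged until no pruned triangle can beat the incumbent).
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import OrientationError


class SurfaceQuery:
    """Exact nearest-point-on-surface queries against a fixed mesh."""

    def __init__(self, mesh: trimesh.Trimesh):
        self.mesh = mesh
        self.triangles = mesh.triangles.view(np.ndarray)
        self._centroids = self.triangles.mean(axis=1)
        # circumscribing bound: max distance from centroid to a triangle vertex
        self._radii = np.linalg.norm(
            self.triangles - self._centroids[:, None, :], axis=2).max(axis=1)
        self._r_max = float(self._radii.max()) if len(self._radii) else 0.0
        self._tree = cKDTree(self._centroids)

    def closest(self, points):
        """Return ``(closest_points, distances, triangle_ids)`` for each query point.

        Exact: a k-nearest-centroid candidate pass is verified with a ball
        query at radius ``best + r_max`` which covers every triangle whose
        centroid bound could still improve the incumbent.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n_tri = len(self.triangles)
        k = min(16, n_tri)
        _, cand = self._tree.query(points, k=k)
        cand = np.atleast_2d(cand)
        flat_pts = np.repeat(points, cand.shape[1], axis=0)
        flat_tris = self.triangles[cand.ravel()]
        near = trimesh.triangles.closest_point(flat_tris, flat_pts)
        d = np.linalg.norm(near - flat_pts, axis=1).reshape(len(points), -1)
        best = d.argmin(axis=1)
        idx = np.arange(len(points))
        dist = d[idx, best]
        tri_id = cand[idx, best]
        close = near.reshape(len(points), -1, 3)[idx, best]

        # verification pass: triangles whose centroid lies within best + r_max
        balls = self._tree.query_ball_point(points, dist + self._r_max + 1e-12)
        for i, ball in enumerate(balls):
            extra = np.setdiff1d(np.asarray(ball, dtype=int), cand[i], assume_unique=False)
            if len(extra) == 0:
                continue
            near_e = trimesh.triangles.closest_point(self.triangles[extra],
                                                     np.repeat(points[i][None], len(extra), axis=0))
            d_e = np.linalg.norm(near_e - points[i], axis=1)
            j = d_e.argmin()
            if d_e[j] < dist[i]:
                dist[i] = d_e[j]
                tri_id[i] = extra[j]
                close[i] = near_e[j]
        return close, dist, tri_id

    def signed_distance(self, points):
        """Perpendicular distance to the surface, signed by the face normal at
        the closest point (positive outside / above the surface)."""
        if not self.mesh.is_winding_consistent:
            raise OrientationError("mesh does not have consistently oriented normals")
        close, dist, tri_id = self.closest(points)
        normals = self.mesh.face_normals[tri_id]
        offset = np.atleast_2d(points) - close
        sign = np.where(np.einsum("ij,ij->i", offset, normals) >= 0.0, 1.0, -1.0)
        return sign * dist, close, tri_id


def ray_hits(mesh: trimesh.Trimesh, origin, direction, eps: float = 1e-9):
    """All intersections of the ray ``origin + t * direction`` (t >= 0) with the mesh.

    Vectorized Moeller-Trumbore over every triangle; returns ``(points, t)``
    sorted by increasing t.  Suitable for single-ray planning queries.
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    tri = mesh.triangles.view(np.ndarray)
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    h = np.cross(direction, e2)
    a = np.einsum("ij,ij->i", e1, h)
    mask = np.abs(a) > eps
    f = np.zeros_like(a)
    f[mask] = 1.0 / a[mask]
    s = origin - v0
    u = f * np.einsum("ij,ij->i", s, h)
    q = np.cross(s, e1)
    v = f * (q @ direction)
    t = f * np.einsum("ij,ij->i", e2, q)
    ok = mask & (u >= -eps) & (v >= -eps) & (u + v <= 1.0 + eps) & (t >= eps)
    t = t[ok]
    order = np.argsort(t)
    t = t[order]
    return origin + t[:, None] * direction, t
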