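"""Internal geometry kernels.

Point-to-surface distance, planar sections, and exact clipped volumes.
These are the numerical primitives behind the similarity metrics and the
regional morphometry; they avoid optional trimesh backends (rtree/embree,
polygon triangulation engines) by working directly from the triangle soup.
"""

from __future__ import annotations

import numpy as np
import trimesh
import trimesh.triangles
from scipy.spatial import cKDTree

from .core import DegenerateGeometryError, ParameterError

_EPS = 1e-12


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, float)
    n = np.linalg.norm(v)
    if n < _EPS:
        raise ParameterError("zero-length vector cannot be normalized")
    return v / n


def polyline_length(points: np.ndarray) -> float:
    points = np.asarray(points, float)
    if len(points) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def cumulative_arc_length(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def sample_points(mesh: trimesh.Trimesh, count: int, seed: int) -> np.ndarray:
    """Uniform-area surface samples, deterministic given seed."""
    pts, _ = trimesh.sample.sample_surface(mesh, int(count), seed=int(seed))
    return np.asarray(pts, float)


class SurfaceDistance:
    """Exact point-to-surface distance queries against one triangle mesh.

    Candidate triangles come from a KD-tree over triangle centroids; the
    candidate set is provably sufficient whenever the best distance found
    is below the k-th centroid distance minus the largest centroid-to-vertex
    radius, and is widened by a ball query otherwise.
    """

    def __init__(self, mesh: trimesh.Trimesh, k: int = 32):
        if len(mesh.faces) == 0:
            raise ParameterError("empty mesh")
        self.mesh = mesh
        self.triangles = mesh.triangles.copy()
        self.face_normals = np.asarray(mesh.face_normals, float)
        self._centroids = self.triangles.mean(axis=1)
        self._radius = float(
            np.linalg.norm(self.triangles - self._centroids[:, None, :], axis=2).max())
        self._tree = cKDTree(self._centroids)
        self._k = int(min(k, len(self.triangles)))

    def _best_of(self, points, cand):
        """cand: (n, m) triangle indices per point -> (dist, closest, tri_idx)."""
        n, m = cand.shape
        flat_tris = self.triangles[cand.ravel()]
        flat_pts = np.repeat(points, m, axis=0)
        closest = trimesh.triangles.closest_point(flat_tris, flat_pts)
        d = np.linalg.norm(closest - flat_pts, axis=1).reshape(n, m)
        j = np.argmin(d, axis=1)
        idx = np.arange(n)
        return (d[idx, j],
                closest.reshape(n, m, 3)[idx, j],
                cand[idx, j])

    def query(self, points: np.ndarray):
        """Return (distance_mm, closest_point, triangle_index) per query point."""
        points = np.atleast_2d(np.asarray(points, float))
        dc, cand = self._tree.query(points, k=self._k)
        if self._k == 1:
            dc = dc[:, None]
            cand = cand[:, None]
        dist, closest, tri = self._best_of(points, cand)
        if self._k < len(self.triangles):
            # widen where the candidate set may have excluded a closer triangle
            unsure = dist > dc[:, -1] - self._radius
            for i in np.nonzero(unsure)[0]:
                ball = self._tree.query_ball_point(points[i], dist[i] + self._radius)
                if len(ball) <= self._k:
                    continue
                d_i, c_i, t_i = self._best_of(points[i:i + 1], np.asarray([ball]))
                dist[i], closest[i], tri[i] = d_i[0], c_i[0], t_i[0]
        return dist, closest, tri

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Positive outside the surface, negative inside (face pseudo-normal)."""
        points = np.atleast_2d(np.asarray(points, float))
        dist, closest, tri = self.query(points)
        sign = np.sign(np.einsum("ij,ij->i", points - closest, self.face_normals[tri]))
        sign[sign == 0] = 1.0
        return dist * sign


# --------------------------------------------------------------------------- #
# planar sections
# --------------------------------------------------------------------------- #

def section_polygons(mesh: trimesh.Trimesh, origin, normal):
    """Shapely polygons of the cross-section plus the planar-to-world 4x4.

    Returns (polygons, to_3D) or None when the plane misses the mesh.
    """
    sec = mesh.section(plane_origin=np.asarray(origin, float),
                       plane_normal=unit(normal))
    if sec is None or len(sec.entities) == 0:
        return None
    planar, to_3d = sec.to_2D()
    polys = list(planar.polygons_full)
    if not polys:
        return None
    return polys, to_3d


def section_area_centroid(mesh, origin, normal, largest_only: bool = False):
    """Cross-section area (mm^2) and area-weighted centroid (world mm).

    Multiple loops are summed unless ``largest_only``; returns None when the
    plane misses the surface.
    """
    got = section_polygons(mesh, origin, normal)
    if got is None:
        return None
    polys, to_3d = got
    if largest_only and len(polys) > 1:
        polys = [max(polys, key=lambda p: p.area)]
    areas = np.array([p.area for p in polys])
    cents = np.array([[p.centroid.x, p.centroid.y] for p in polys])
    area = float(areas.sum())
    if area <= _EPS:
        return None
    c2 = (cents * areas[:, None]).sum(axis=0) / area
    c3 = (to_3d @ np.array([c2[0], c2[1], 0.0, 1.0]))[:3]
    return area, c3


# --------------------------------------------------------------------------- #
# clipped volumes
# --------------------------------------------------------------------------- #

def _clip_triangles(tris: np.ndarray, origin, normal) -> np.ndarray:
    """Clip a triangle soup to the half-space dot(x - origin, normal) >= 0."""
    tris = np.asarray(tris, float)
    if len(tris) == 0:
        return tris.reshape(0, 3, 3)
    n = unit(normal)
    s = (tris - np.asarray(origin, float)) @ n  # (m, 3) signed distances
    inside = s >= 0.0
    count = inside.sum(axis=1)

    out = [tris[count == 3]]

    def lerp(a, b, sa, sb):
        t = (sa / (sa - sb))[:, None]
        return a + t * (b - a)

    # one vertex inside -> single triangle (A, P_AB, P_CA)
    m1 = count == 1
    if m1.any():
        t1, s1, in1 = tris[m1], s[m1], inside[m1]
        shift = np.argmax(in1, axis=1)
        cols = (shift[:, None] + np.arange(3)) % 3
        t1 = np.take_along_axis(t1, cols[:, :, None], axis=1)
        s1 = np.take_along_axis(s1, cols, axis=1)
        A, B, C = t1[:, 0], t1[:, 1], t1[:, 2]
        p_ab = lerp(A, B, s1[:, 0], s1[:, 1])
        p_ca = lerp(C, A, s1[:, 2], s1[:, 0])
        out.append(np.stack([A, p_ab, p_ca], axis=1))

    # two vertices inside -> quad A,B,P_BC,P_CA split into two triangles
    m2 = count == 2
    if m2.any():
        t2, s2, in2 = tris[m2], s[m2], inside[m2]
        shift = np.argmax(~in2, axis=1)  # C = the outside vertex
        cols = (shift[:, None] + np.arange(1, 4)) % 3  # order A, B, C(out)
        t2 = np.take_along_axis(t2, cols[:, :, None], axis=1)
        s2 = np.take_along_axis(s2, cols, axis=1)
        A, B, C = t2[:, 0], t2[:, 1], t2[:, 2]
        p_bc = lerp(B, C, s2[:, 1], s2[:, 2])
        p_ca = lerp(C, A, s2[:, 2], s2[:, 0])
        out.append(np.stack([A, B, p_bc], axis=1))
        out.append(np.stack([A, p_bc, p_ca], axis=1))

    return np.concatenate(out, axis=0)


def slab_volume(mesh: trimesh.Trimesh, planes) -> float:
    """Volume (mm^3) of the mesh interior kept by every half-space in ``planes``.

    ``planes`` is a sequence of (origin, normal) with the normal pointing into
    the kept region. Planar cuts are closed analytically: each cap contributes
    its cone flux -(origin . n) * A / 3, with A the cross-section area of the
    mesh at that plane — exact when the cutting planes do not intersect each
    other inside the solid, which holds for stations along a muscle pathway.
    """
    tris = mesh.triangles.copy()
    cap = 0.0
    for origin, normal in planes:
        n = unit(normal)
        origin = np.asarray(origin, float)
        tris = _clip_triangles(tris, origin, n)
        got = section_area_centroid(mesh, origin, n)
        if got is not None:
            area, _ = got
            cap += -(origin @ n) * area / 3.0
    if len(tris) == 0:
        return 0.0
    flux = float(np.einsum("ij,ij->", np.cross(tris[:, 0], tris[:, 1]), tris[:, 2])) / 6.0
    return flux + cap


def require_watertight(mesh: trimesh.Trimesh, what: str = "mesh") -> trimesh.Trimesh:
    """Validate closedness/orientation, attempting a light repair first."""
    if not mesh.is_watertight:
        mesh = mesh.copy()
        mesh.process(validate=True)
        mesh.fill_holes()
        if not mesh.is_watertight:
            raise DegenerateGeometryError(f"{what} is not watertight")
    if mesh.volume < 0:
        mesh = mesh.copy()
        mesh.invert()
    return mesh
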