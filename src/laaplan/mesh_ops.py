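"""Triangulated-surface geometry kernel.

Surface meshes of the left atrial appendage wall live in patient
coordinates (mm).  This module provides their I/O, rigid motion and
point-based registration, ray and plane intersection, and the planar
polygon metrics (perimeter, area, caliper diameters) that the sizing
computations are built on.  trimesh does the heavy lifting for file
formats and accelerated intersection queries; the measurement logic is
implemented here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .carm import Ray

__all__ = [
    "SurfaceMesh",
    "RigidTransform",
    "PlanarSection",
    "load_mesh",
    "save_mesh",
    "apply_transform",
    "register_points",
    "intersect_ray_mesh",
    "plane_section",
    "plane_basis",
    "polygon_perimeter",
    "polygon_area",
    "polygon_max_diameter",
    "polygon_min_width",
]

_DEGEN_AREA_MM2 = 1e-12
_HIT_DEDUP_MM = 1e-6  # grazing/duplicate intersection tolerance


@dataclass
class SurfaceMesh:
    """Triangulated surface in patient mm: (n,3) vertices, (m,3) face indices."""

    vertices: np.ndarray
    faces: np.ndarray
    _trimesh: trimesh.Trimesh | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError(f"vertices must be (n, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError(f"faces must be (m, 3), got {f.shape}")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face indices out of range")
        a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
        areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
        if f.size and (areas <= _DEGEN_AREA_MM2).any():
            raise ValueError(
                f"{int((areas <= _DEGEN_AREA_MM2).sum())} degenerate (zero-area) faces"
            )
        self.vertices, self.faces = v, f

    def as_trimesh(self) -> trimesh.Trimesh:
        if self._trimesh is None:
            self._trimesh = trimesh.Trimesh(
                vertices=self.vertices, faces=self.faces, process=False
            )
        return self._trimesh

    @property
    def is_watertight(self) -> bool:
        return bool(self.as_trimesh().is_watertight)

    def check_watertight(self, context: str = "sectioning") -> None:
        if not self.is_watertight:
            warnings.warn(
                f"mesh is not watertight; {context} may be unreliable", stacklevel=3
            )

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation 3x3, translation mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if r.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {r.shape}")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = p @ self.rotation.T + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def to_json(self) -> str:
        return json.dumps({"matrix": self.matrix().tolist()})

    @classmethod
    def from_json(cls, s: str) -> "RigidTransform":
        m = np.asarray(json.loads(s)["matrix"], dtype=float)
        return cls(m[:3, :3], m[:3, 3])


@dataclass
class PlanarSection:
    """Cross-section of a surface by a plane.

    ``polygons`` are closed 2D loops (first vertex not repeated) in the
    in-plane coordinate system spanned by ``in_plane_axes``; they are
    ordered by descending enclosed area.  A loop's 3D vertices are
    ``plane_point + x*axis0 + y*axis1``.
    """

    plane_point: np.ndarray
    plane_normal: np.ndarray
    in_plane_axes: tuple[np.ndarray, np.ndarray]
    polygons: list[np.ndarray]

    def __post_init__(self):
        self.plane_point = np.asarray(self.plane_point, dtype=float).reshape(3)
        n = np.asarray(self.plane_normal, dtype=float).reshape(3)
        self.plane_normal = n / np.linalg.norm(n)
        a0, a1 = (np.asarray(a, dtype=float).reshape(3) for a in self.in_plane_axes)
        for v, w in ((a0, a1), (a0, self.plane_normal), (a1, self.plane_normal)):
            if abs(v @ w) > 1e-9:
                raise ValueError("in-plane axes must be orthonormal and normal to the plane")
        self.in_plane_axes = (a0, a1)
        self.polygons = [np.asarray(p, dtype=float) for p in self.polygons]
        for p in self.polygons:
            if p.ndim != 2 or p.shape[1] != 2 or len(p) < 3:
                raise ValueError("each polygon must be a closed 2D loop with >= 3 vertices")

    def loop_points_3d(self, i: int = 0) -> np.ndarray:
        a0, a1 = self.in_plane_axes
        poly = self.polygons[i]
        return self.plane_point + np.outer(poly[:, 0], a0) + np.outer(poly[:, 1], a1)

    def loop_centroid_3d(self, i: int = 0) -> np.ndarray:
        return self.loop_points_3d(i).mean(axis=0)


# --- I/O -------------------------------------------------------------------

def load_mesh(path) -> SurfaceMesh:
    """Load an STL or PLY surface (vertices in mm, patient coordinates)."""
    try:
        tm = trimesh.load_mesh(str(path))
    except Exception as exc:  # noqa: BLE001 - file format errors vary
        raise ValueError(f"could not read mesh from {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise ValueError(f"no triangulated surface found in {path}")
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def save_mesh(mesh: SurfaceMesh, path) -> None:
    mesh.as_trimesh().export(str(path))


# --- rigid motion ----------------------------------------------------------

def apply_transform(mesh: SurfaceMesh, t: RigidTransform) -> SurfaceMesh:
    """Apply a rigid motion to every vertex; connectivity is unchanged."""
    return SurfaceMesh(t.apply(mesh.vertices), mesh.faces.copy())


def register_points(source, target) -> tuple[RigidTransform, float]:
    """Least-squares rigid registration of paired 3D points (Kabsch/SVD).

    Finds the proper rotation + translation minimizing
    sum ||R s_i + t - t_i||^2 and returns it with the RMS residual.
    Reflections are rejected by sign-correcting the smallest singular
    vector, so the result is always a physical rigid motion.  Stands in
    for the interactive mesh-to-XR registration step of the clinical
    workflow when corresponding fiducials are available.
    """
    s = np.asarray(source, dtype=float)
    t = np.asarray(target, dtype=float)
    if s.shape != t.shape or s.ndim != 2 or s.shape[1] != 3:
        raise ValueError("source and target must be equal-shaped (n, 3) arrays")
    if len(s) < 3:
        raise ValueError("need at least 3 point pairs")
    sc, tc = s.mean(axis=0), t.mean(axis=0)
    s0, t0 = s - sc, t - tc
    # collinearity check: centered source must span a plane
    if np.linalg.matrix_rank(s0, tol=1e-9 * max(1.0, np.abs(s0).max())) < 2:
        raise ValueError("source points are collinear; rotation is underdetermined")
    h = s0.T @ t0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = tc - r @ sc
    tfm = RigidTransform(r, trans)
    rms = float(np.sqrt(np.mean(np.sum((tfm.apply(s) - t) ** 2, axis=1))))
    return tfm, rms


# --- intersection ----------------------------------------------------------

def _ray_triangle_hits(vertices: np.ndarray, faces: np.ndarray,
                       origin: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Ray parameters t >= 0 of all triangle intersections (Moller-Trumbore).

    Fully vectorized over triangles; edge/vertex contacts are included
    (barycentric tolerance 1e-12) and the caller deduplicates the
    duplicate hits this produces on shared edges.
    """
    v0 = vertices[faces[:, 0]]
    e1 = vertices[faces[:, 1]] - v0
    e2 = vertices[faces[:, 2]] - v0
    pvec = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > 1e-14
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = origin - v0
    u = np.einsum("ij,ij->i", tvec, pvec) * inv
    qvec = np.cross(tvec, e1)
    v = np.einsum("j,ij->i", direction, qvec) * inv
    t = np.einsum("ij,ij->i", e2, qvec) * inv
    eps = 1e-12
    hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1.0 + eps) & (t >= -eps)
    return t[hit]


def intersect_ray_mesh(mesh: SurfaceMesh, ray: Ray) -> np.ndarray:
    """All ray-triangle intersection points, sorted by distance from origin.

    Grazing hits at shared triangle edges are deduplicated within 1e-6 mm
    so a projection line crossing a closed wall yields one point per wall
    passage.  Returns an empty (0, 3) array when the ray misses.
    """
    t = _ray_triangle_hits(mesh.vertices, mesh.faces, ray.origin, ray.direction)
    if len(t) == 0:
        return np.empty((0, 3))
    t = np.sort(t)
    keep = np.ones(len(t), dtype=bool)
    keep[1:] = np.diff(t) > _HIT_DEDUP_MM
    t = t[keep]
    return ray.origin + t[:, None] * ray.direction


def plane_basis(normal) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal in-plane axes for a given plane normal."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    helper = np.array([0.0, 0.0, 1.0]) if abs(n[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    a0 = np.cross(helper, n)
    a0 /= np.linalg.norm(a0)
    a1 = np.cross(n, a0)
    return a0, a1


def plane_section(mesh: SurfaceMesh, plane_point, plane_normal) -> PlanarSection:
    """Intersect the surface with a plane, returning all closed loops.

    Loops are projected to 2D plane coordinates and ordered by descending
    enclosed area; lobed anatomies can produce several loops and the
    caller selects among them.  Raises ``ValueError`` when the plane
    misses the mesh or only yields degenerate open traces.
    """
    plane_point = np.asarray(plane_point, dtype=float).reshape(3)
    n = np.asarray(plane_normal, dtype=float).reshape(3)
    n = n / np.linalg.norm(n)
    mesh.check_watertight(context="plane sectioning")
    path = mesh.as_trimesh().section(plane_origin=plane_point, plane_normal=n)
    if path is None:
        raise ValueError("plane does not intersect the mesh")
    a0, a1 = plane_basis(n)
    polys = []
    for loop3d in path.discrete:
        pts = np.asarray(loop3d, dtype=float)
        closed = np.allclose(pts[0], pts[-1], atol=1e-9)
        if closed:
            pts = pts[:-1]
        if len(pts) < 3 or not closed:
            continue
        rel = pts - plane_point
        polys.append(np.column_stack([rel @ a0, rel @ a1]))
    if not polys:
        raise ValueError("plane intersection produced no closed loop")
    polys.sort(key=polygon_area, reverse=True)
    return PlanarSection(plane_point, n, (a0, a1), polys)


# --- polygon metrics -------------------------------------------------------

def _check_loop(poly) -> np.ndarray:
    p = np.asarray(poly, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or len(p) < 3:
        raise ValueError("polygon must be an (n>=3, 2) closed loop")
    if polygon_area(p) <= _DEGEN_AREA_MM2:
        raise ValueError("degenerate polygon (zero enclosed area)")
    return p


def polygon_perimeter(poly) -> float:
    """Sum of edge lengths of the closed loop (mm)."""
    p = np.asarray(poly, dtype=float)
    return float(np.linalg.norm(np.diff(np.vstack([p, p[:1]]), axis=0), axis=1).sum())


def polygon_area(poly) -> float:
    """Enclosed area by the shoelace formula (mm^2), orientation-independent."""
    p = np.asarray(poly, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def _hull_vertices(poly: np.ndarray) -> np.ndarray:
    from scipy.spatial import ConvexHull

    return poly[ConvexHull(poly).vertices]


def polygon_max_diameter(poly) -> tuple[float, np.ndarray]:
    """Maximum caliper diameter of the loop and its unit direction.

    The maximum chord of a closed region equals that of its convex hull,
    so the search runs over hull vertices only — this also makes the
    measure robust to concave digitization noise, matching how calipers
    are placed on a clinical image.
    """
    p = _check_loop(poly)
    h = _hull_vertices(p)
    d2 = np.sum((h[:, None, :] - h[None, :, :]) ** 2, axis=-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    vec = h[j] - h[i]
    return float(np.sqrt(d2[i, j])), vec / np.linalg.norm(vec)


def polygon_min_width(poly) -> float:
    """Minimum support width of the loop by rotating calipers (mm).

    For a convex polygon the minimal width is attained with one caliper
    flush against an edge, so it suffices to scan hull edges and take the
    farthest-vertex distance for each.
    """
    p = _check_loop(poly)
    h = _hull_vertices(p)
    edges = np.roll(h, -1, axis=0) - h
    lens = np.linalg.norm(edges, axis=1)
    good = lens > 1e-12
    edges, origins, lens = edges[good], h[good], lens[good]
    normals = np.column_stack([-edges[:, 1], edges[:, 0]]) / lens[:, None]
    # distance of every hull vertex from every edge line
    d = np.abs((h[None, :, :] - origins[:, None, :]) @ normals[:, :, None]).squeeze(-1)
    return float(d.max(axis=1).min())
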