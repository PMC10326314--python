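"""Landing-zone localization and multiplanar reconstruction.

The landing zone — the appendage cross-section where an occluder device
anchors — is annotated periprocedurally as a 2D diameter on a fluoroscopy
frame.  Given the registered 3D surface mesh and the C-arm pose of that
frame, the two annotation endpoints are localized in 3D by intersecting
their back-projected rays with the mesh; the cross-section plane spanned
by the recovered diameter and the beam direction then supports sizing
directly on the mesh and image reformatting (MPR) at the same anatomical
location.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .carm import CArmPose, backproject_line, viewing_direction
from .mesh_ops import (
    PlanarSection,
    SurfaceMesh,
    intersect_ray_mesh,
    plane_section,
    polygon_max_diameter,
)

__all__ = [
    "LandingZone",
    "ImageVolume",
    "MprImage",
    "localize_landing_zone",
    "landing_plane",
    "mpr_resample",
    "measure_cross_section",
    "projected_diameter",
]


@dataclass
class LandingZone:
    """A localized landing zone: two wall points and the section plane."""

    endpoint_a: np.ndarray
    endpoint_b: np.ndarray
    plane_point: np.ndarray
    plane_normal: np.ndarray
    source_pose: CArmPose

    def __post_init__(self):
        for name in ("endpoint_a", "endpoint_b", "plane_point", "plane_normal"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        seg = self.endpoint_b - self.endpoint_a
        if abs(seg @ self.plane_normal) > 1e-6 * max(1.0, np.linalg.norm(seg)):
            raise ValueError("plane normal is not orthogonal to the landing-zone segment")

    @property
    def diameter_mm(self) -> float:
        return float(np.linalg.norm(self.endpoint_b - self.endpoint_a))


@dataclass
class ImageVolume:
    """3D scalar volume with spacing (mm), origin and axis directions.

    World position of voxel index (i, j, k) is
    ``origin + direction @ (spacing * (i, j, k))`` (center-of-voxel,
    0-based) — the NIfTI/DICOM convention.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.data.ndim}D")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if (self.spacing <= 0).any():
            raise ValueError("voxel spacing must be positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if not np.allclose(d.T @ d, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix must be orthonormal")
        self.direction = d

    def world_to_index(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return ((p - self.origin) @ self.direction) / self.spacing

    @classmethod
    def from_nifti(cls, path) -> "ImageVolume":
        import nibabel as nib

        img = nib.load(str(path))
        aff = img.affine.copy()
        # nibabel affines are RAS; patient frame here is LPS
        aff[:2] *= -1.0
        m = aff[:3, :3]
        spacing = np.linalg.norm(m, axis=0)
        return cls(
            data=np.asarray(img.get_fdata()),
            spacing=spacing,
            origin=aff[:3, 3],
            direction=m / spacing,
        )

    def to_nifti(self, path) -> None:
        import nibabel as nib

        aff = np.eye(4)
        aff[:3, :3] = self.direction * self.spacing
        aff[:3, 3] = self.origin
        aff[:2] *= -1.0  # LPS -> RAS for NIfTI
        nib.save(nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), aff), str(path))


@dataclass
class MprImage:
    """A reformatted 2D image with the plane frame mapping pixels to 3D."""

    data: np.ndarray
    spacing_mm: float
    plane_point: np.ndarray
    plane_axes: tuple[np.ndarray, np.ndarray]

    def pixel_to_world(self, rc) -> np.ndarray:
        r, c = np.asarray(rc, dtype=float)
        a0, a1 = self.plane_axes
        h, w = self.data.shape
        x = (c - (w - 1) / 2.0) * self.spacing_mm
        y = (r - (h - 1) / 2.0) * self.spacing_mm
        return self.plane_point + x * a0 + y * a1


def landing_plane(endpoint_a, endpoint_b, view_dir) -> tuple[np.ndarray, np.ndarray]:
    """Cross-section plane through a measured diameter.

    The plane contains both endpoints and the beam direction:
    ``normal = normalize((b - a) x view)``, anchored at the segment
    midpoint.  Under the tangential (edge-on) view used clinically, the
    measured diameter and the beam both lie in the anatomical
    cross-section plane, so this construction reconstructs it.
    """
    a = np.asarray(endpoint_a, dtype=float).reshape(3)
    b = np.asarray(endpoint_b, dtype=float).reshape(3)
    v = np.asarray(view_dir, dtype=float).reshape(3)
    seg = b - a
    seg_len = np.linalg.norm(seg)
    if seg_len < 1e-9:
        raise ValueError("landing-zone endpoints coincide")
    n = np.cross(seg, v)
    n_len = np.linalg.norm(n)
    if n_len < 1e-9 * seg_len * np.linalg.norm(v):
        raise ValueError("landing-zone segment is parallel to the viewing direction")
    return (a + b) / 2.0, n / n_len


def _grazing_capture(mesh: SurfaceMesh, ray, capture_mm: float) -> np.ndarray:
    """Nearest surface vertex to the ray, if within the capture radius.

    Annotation endpoints sit on the anatomy's silhouette, so their
    projection lines are tangent to the wall: exact triangle intersection
    is numerically fragile there, and a slightly outward annotation click
    misses the surface entirely.  Both are resolved by capturing the
    closest wall vertex to the ray, mirroring how a reader's click on the
    silhouette is meant.
    """
    w = mesh.vertices - ray.origin
    t = w @ ray.direction
    ahead = t > 0
    if not ahead.any():
        return np.empty((0, 3))
    d = np.linalg.norm(w[ahead] - np.outer(t[ahead], ray.direction), axis=1)
    i = int(np.argmin(d))
    if d[i] > capture_mm:
        return np.empty((0, 3))
    return mesh.vertices[ahead][i][None, :]


def localize_landing_zone(
    mesh: SurfaceMesh, pose: CArmPose, q_a, q_b, capture_mm: float = 2.0
) -> LandingZone:
    """Localize a 2D fluoroscopic diameter annotation in 3D on the mesh.

    Each detector endpoint is back-projected into a projection line and
    intersected with the surface.  A tubular wall yields several hits per
    ray; since the two endpoints of a measured diameter lie on opposite
    walls at (nearly) the same depth, the returned pair is the one
    minimizing the absolute depth difference along the beam.  A ray that
    misses the surface outright (tangential silhouette annotations do,
    within a pixel) falls back to the nearest wall vertex within
    ``capture_mm``.

    Raises ``ValueError`` naming the endpoint whose ray misses the mesh.
    """
    v = viewing_direction(pose)
    hits = []
    for label, q in (("A", q_a), ("B", q_b)):
        ray = backproject_line(pose, q)
        h = intersect_ray_mesh(mesh, ray)
        if len(h) == 0 and capture_mm > 0:
            h = _grazing_capture(mesh, ray, capture_mm)
        if len(h) == 0:
            raise ValueError(f"ray {label} misses mesh")
        hits.append(h)
    depth_a, depth_b = hits[0] @ v, hits[1] @ v
    disparity = np.abs(depth_a[:, None] - depth_b[None, :])
    i, j = np.unravel_index(np.argmin(disparity), disparity.shape)
    a, b = hits[0][i], hits[1][j]
    point, normal = landing_plane(a, b, v)
    return LandingZone(a, b, point, normal, pose)


def mpr_resample(
    volume: ImageVolume,
    plane_point,
    plane_axes,
    fov_mm: float = 60.0,
    spacing_mm: float = 0.5,
    fill_value: float = 0.0,
) -> MprImage:
    """Reformat the volume on an arbitrary plane (multiplanar reconstruction).

    Samples the volume by trilinear interpolation on a square pixel grid
    centered at ``plane_point`` and spanned by the two orthonormal
    ``plane_axes``; pixels outside the volume take ``fill_value``.
    Trilinear interpolation reproduces any affine intensity field exactly,
    which the tests exploit.
    """
    from scipy.ndimage import map_coordinates

    point = np.asarray(plane_point, dtype=float).reshape(3)
    a0, a1 = (np.asarray(a, dtype=float).reshape(3) for a in plane_axes)
    for v, w in ((a0, a0), (a1, a1)):
        if abs(v @ w - 1.0) > 1e-6:
            raise ValueError("plane axes must be unit length")
    if abs(a0 @ a1) > 1e-6:
        raise ValueError("plane axes must be orthogonal")
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    n = max(2, int(round(fov_mm / spacing_mm)) + 1)
    offs = (np.arange(n) - (n - 1) / 2.0) * spacing_mm
    yy, xx = np.meshgrid(offs, offs, indexing="ij")
    pts = point + xx[..., None] * a0 + yy[..., None] * a1
    idx = volume.world_to_index(pts.reshape(-1, 3)).T  # (3, n*n) in voxel indices
    img = map_coordinates(
        np.asarray(volume.data, dtype=float),
        idx,
        order=1,
        mode="constant",
        cval=fill_value,
    ).reshape(n, n)
    return MprImage(img, float(spacing_mm), point, (a0, a1))


def measure_cross_section(mesh: SurfaceMesh, zone: LandingZone) -> PlanarSection:
    """Section the mesh with the landing-zone plane and pick the right loop.

    Lobed anatomies (and end caps of phantom tubes) produce multiple
    closed loops; the loop whose centroid is nearest the landing-zone
    midpoint is the anatomical cross-section of interest, regardless of
    its area rank.
    """
    section = plane_section(mesh, zone.plane_point, zone.plane_normal)
    dists = [
        np.linalg.norm(section.loop_centroid_3d(i) - zone.plane_point)
        for i in range(len(section.polygons))
    ]
    best = int(np.argmin(dists))
    if best != 0:
        section.polygons.insert(0, section.polygons.pop(best))
    return section


def projected_diameter(section: PlanarSection, pose: CArmPose) -> float:
    """Diameter of the section as seen in a given projection (mm).

    Projects the selected loop's 3D vertices onto the plane perpendicular
    to the beam and returns the maximum pairwise distance — the length a
    caliper would read on the fluoroscopy frame, foreshortening included.
    """
    pts = section.loop_points_3d(0)
    if len(pts) < 3:
        raise ValueError("degenerate section loop")
    v = viewing_direction(pose)
    proj = pts - np.outer(pts @ v, v)
    # max chord of the projected loop = max chord of its 2D convex hull
    basis = np.linalg.svd(proj - proj.mean(axis=0), full_matrices=False)[2][:2]
    flat = (proj - proj.mean(axis=0)) @ basis.T
    from scipy.spatial import QhullError

    try:
        d, _ = polygon_max_diameter(flat)
    except (ValueError, QhullError):
        # edge-on view collapses the loop to a segment; use raw extent
        d2 = np.sum((flat[:, None, :] - flat[None, :, :]) ** 2, axis=-1)
        d = float(np.sqrt(d2.max()))
    return d
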