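"""C-arm fluoroscopy imaging geometry.

Models the gantry of an interventional X-ray system as a pinhole
(cone-beam) camera: primary/secondary angulation define the central beam
direction in the patient frame, and the source-to-isocenter (SOD) and
source-to-detector (SID) distances define the perspective magnification.

Conventions
-----------
* Patient coordinates are DICOM LPS: +x left, +y posterior, +z superior.
* Primary angle ``alpha``: positive = LAO (beam exits toward the patient's
  left), negative = RAO.  Secondary angle ``beta``: positive = CRAN,
  negative = CAUD.  This is the DICOM C-arm positioner convention, so the
  clinically recommended working projection RAO20-30/CAUD20-30 maps to
  ``alpha in [-30, -20]``, ``beta in [-30, -20]``.
* The viewing direction is the unit vector from source toward detector:

      v(alpha, beta) = (sin a cos b, -cos a cos b, sin b)

  so the frontal AP beam (0, 0) looks along (0, -1, 0).
* Detector in-plane coordinates are measured in mm from the principal
  point (where the central beam hits the detector).  The row axis is the
  horizontal patient axis rotated by alpha, ``u = (cos a, sin a, 0)``;
  the column axis ``c = v x u`` completes a right-handed frame and points
  superior for the AP view.
* ``sid_mm = inf`` selects an orthographic (parallel) projection, useful
  for analytic tests; real acquisitions are always perspective.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "CArmPose",
    "Ray",
    "viewing_direction",
    "pose_from_direction",
    "detector_frame",
    "project_point",
    "backproject_line",
    "angular_difference",
    "read_xr_geometry",
    "write_xr_geometry",
]

_UNIT_TOL = 1e-9


def _as_vec3(p, name: str = "point") -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class CArmPose:
    """Gantry angulation plus the distances of the projective geometry.

    Parameters
    ----------
    alpha_deg : primary angulation (deg); positive = LAO, negative = RAO.
    beta_deg : secondary angulation (deg); positive = CRAN, negative = CAUD.
    sod_mm : source-to-isocenter distance (mm).
    sid_mm : source-to-detector distance (mm); ``inf`` = parallel projection.
    pixel_spacing_mm : detector sampling pitch, (row, column) in mm.
    """

    alpha_deg: float = 0.0
    beta_deg: float = 0.0
    sod_mm: float = 765.0
    sid_mm: float = 1100.0
    pixel_spacing_mm: tuple[float, float] = (0.308, 0.308)

    def __post_init__(self):
        if not (-180.0 < self.alpha_deg <= 180.0):
            raise ValueError(f"alpha_deg must be in (-180, 180], got {self.alpha_deg}")
        if not (-90.0 <= self.beta_deg <= 90.0):
            raise ValueError(f"beta_deg must be in [-90, 90], got {self.beta_deg}")
        if not (self.sid_mm > self.sod_mm > 0):
            raise ValueError(
                f"need sid_mm > sod_mm > 0, got sid={self.sid_mm}, sod={self.sod_mm}"
            )
        ps = self.pixel_spacing_mm
        ps = (float(ps), float(ps)) if np.isscalar(ps) else (float(ps[0]), float(ps[1]))
        if min(ps) <= 0:
            raise ValueError(f"pixel_spacing_mm must be positive, got {ps}")
        object.__setattr__(self, "pixel_spacing_mm", ps)

    @property
    def is_parallel(self) -> bool:
        return math.isinf(self.sid_mm)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "CArmPose":
        d = json.loads(s)
        d["pixel_spacing_mm"] = tuple(d["pixel_spacing_mm"])
        return cls(**d)


@dataclass(frozen=True)
class Ray:
    """A projection line: origin plus unit direction, in patient mm."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        o = _as_vec3(self.origin, "origin")
        d = _as_vec3(self.direction, "direction")
        n = np.linalg.norm(d)
        if abs(n - 1.0) > _UNIT_TOL:
            raise ValueError(f"direction must be unit length, |d| = {n}")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)

    def point_at(self, t: float) -> np.ndarray:
        return self.origin + t * self.direction

    def distance_to_point(self, p) -> float:
        w = _as_vec3(p) - self.origin
        return float(np.linalg.norm(w - (w @ self.direction) * self.direction))


def viewing_direction(pose: CArmPose) -> np.ndarray:
    """Central beam direction (source toward detector) in patient LPS."""
    a = math.radians(pose.alpha_deg)
    b = math.radians(pose.beta_deg)
    return np.array(
        [math.sin(a) * math.cos(b), -math.cos(a) * math.cos(b), math.sin(b)]
    )


def pose_from_direction(v, **pose_kwargs) -> CArmPose:
    """Invert :func:`viewing_direction`: angulation whose beam points along v.

    At |beta| = 90 (beam along the patient axis) the primary angle is
    degenerate and reported as 0.  Extra keyword arguments (distances,
    pixel spacing) are forwarded to :class:`CArmPose`.
    """
    v = _as_vec3(v, "direction")
    n = np.linalg.norm(v)
    if abs(n - 1.0) > 1e-6:
        raise ValueError(f"direction must be unit length, |v| = {n}")
    v = v / n
    beta = math.degrees(math.asin(np.clip(v[2], -1.0, 1.0)))
    if abs(abs(beta) - 90.0) < 1e-9 or math.hypot(v[0], v[1]) < 1e-12:
        alpha = 0.0
        beta = math.copysign(90.0, v[2])
    else:
        alpha = math.degrees(math.atan2(v[0], -v[1]))
    if alpha <= -180.0:
        alpha += 360.0
    return CArmPose(alpha_deg=alpha, beta_deg=beta, **pose_kwargs)


def detector_frame(pose: CArmPose) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (row axis u, column axis c, beam v) — a right-handed triad.

    u is the horizontal patient axis rotated by alpha and is always
    orthogonal to the beam; c = v x u points superior for the AP view.
    """
    a = math.radians(pose.alpha_deg)
    v = viewing_direction(pose)
    u = np.array([math.cos(a), math.sin(a), 0.0])
    c = np.cross(v, u)
    return u, c, v


def source_position(pose: CArmPose) -> np.ndarray:
    """Focal-spot position: sod_mm upstream of the isocenter along the beam."""
    return -pose.sod_mm * viewing_direction(pose)


def project_point(pose: CArmPose, p) -> np.ndarray:
    """Perspective-project a 3D patient point onto the detector.

    Returns in-plane detector coordinates (mm) relative to the principal
    point.  The point must lie strictly downstream of the source; points at
    or behind the focal spot have no image and raise ``ValueError``.  In
    parallel mode the projection is orthographic onto the plane through the
    isocenter.
    """
    p = _as_vec3(p)
    u, c, v = detector_frame(pose)
    if pose.is_parallel:
        return np.array([p @ u, p @ c])
    s = source_position(pose)
    w = p - s
    depth = w @ v
    if depth <= 1e-9:
        raise ValueError(f"point at or behind the X-ray source (depth {depth:.3g} mm)")
    mag = pose.sid_mm / depth
    return np.array([mag * (w @ u), mag * (w @ c)])


def backproject_line(pose: CArmPose, q) -> Ray:
    """Projection line through detector point q (mm from principal point).

    The ray starts at the source and is oriented source -> detector; this
    is the line whose intersections with the anatomy surface localize a 2D
    annotation in 3D.  In parallel mode the ray runs along the beam through
    the isocenter-plane point at q.
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (2,):
        raise ValueError(f"detector point must be 2D, got shape {q.shape}")
    u, c, v = detector_frame(pose)
    if pose.is_parallel:
        origin = q[0] * u + q[1] * c - pose.sod_mm * v
        return Ray(origin=origin, direction=v)
    s = source_position(pose)
    det_pt = s + pose.sid_mm * v + q[0] * u + q[1] * c
    d = det_pt - s
    return Ray(origin=s, direction=d / np.linalg.norm(d))


def angular_difference(a: CArmPose, b: CArmPose) -> float:
    """3D angle (deg) between the two beams, in [0, 180].

    Computed on the viewing-direction vectors, not by subtracting
    (alpha, beta) pairs — angulation coordinates are not an isometric
    parameterization of the viewing sphere.
    """
    cosang = float(np.clip(viewing_direction(a) @ viewing_direction(b), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


# --- DICOM XR geometry -----------------------------------------------------

_DICOM_ATTRS = {
    "PositionerPrimaryAngle": "alpha_deg",
    "PositionerSecondaryAngle": "beta_deg",
    "DistanceSourceToPatient": "sod_mm",
    "DistanceSourceToDetector": "sid_mm",
    "ImagerPixelSpacing": "pixel_spacing_mm",
}


def read_xr_geometry(dicom_path) -> CArmPose:
    """Read the C-arm pose from the positioner attributes of an XR image.

    Uses the DICOM positioner sign convention directly (primary positive =
    LAO, secondary positive = CRAN), which matches this package's own.
    Raises ``ValueError`` naming the first missing required attribute.
    """
    import pydicom

    ds = pydicom.dcmread(str(dicom_path), stop_before_pixels=True, force=True)
    vals = {}
    for attr, field in _DICOM_ATTRS.items():
        if getattr(ds, attr, None) is None:
            raise ValueError(f"{attr} absent in {dicom_path}")
        vals[field] = getattr(ds, attr)
    return CArmPose(
        alpha_deg=float(vals["alpha_deg"]),
        beta_deg=float(vals["beta_deg"]),
        sod_mm=float(vals["sod_mm"]),
        sid_mm=float(vals["sid_mm"]),
        pixel_spacing_mm=tuple(float(x) for x in vals["pixel_spacing_mm"]),
    )


def write_xr_geometry(pose: CArmPose, dicom_path) -> None:
    """Write a minimal XR DICOM carrying only the positioner geometry.

    Intended for round-trip testing and for exporting poses to tools that
    read DICOM; no pixel data is stored.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.XRayAngiographicImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "XA"
    ds.PositionerPrimaryAngle = pose.alpha_deg
    ds.PositionerSecondaryAngle = pose.beta_deg
    ds.DistanceSourceToPatient = pose.sod_mm
    ds.DistanceSourceToDetector = pose.sid_mm
    ds.ImagerPixelSpacing = list(pose.pixel_spacing_mm)
    ds.save_as(str(dicom_path), enforce_file_format=True)
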