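"""Synthetic appendage phantoms with analytic ground truth.

Patient imaging data of this kind are access-restricted, so validation
runs on parametric phantoms: tubular anatomies swept along a straight or
circular-arc centerline with an elliptical, linearly tapering, optionally
twisting cross-section.  Ellipse sweeps are deliberately simple — every
downstream quantity (diameters, perimeter, area, ovality, the optimal
tangential view) has a closed-form or quadrature ground truth, so the
whole pipeline can be checked as parameter recovery.

The phantom is oriented in patient coordinates so that its designated
landing-zone cross-section is viewed tangentially from a configurable
C-arm pose (default RAO25/CAUD25, the center of the clinically
recommended working projection), which mirrors how the real anatomies
are imaged.  Voxelized volumes default to 1.3 mm isotropic spacing, the
resolution of the tomographic acquisitions being emulated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ellipe

from .agreement import PairedMeasurements, RatingsMatrix
from .angulation import optimal_angulation
from .carm import CArmPose, Ray, project_point, viewing_direction
from .landing_zone import ImageVolume
from .mesh_ops import SurfaceMesh, intersect_ray_mesh

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_mesh",
    "voxelize",
    "simulate_annotation",
    "simulate_reader_panel",
]

DEFAULT_POSE = CArmPose(alpha_deg=-25.0, beta_deg=-25.0)


def _lerp(lo: float, hi: float, s) -> np.ndarray:
    return lo + (hi - lo) * np.asarray(s, dtype=float)


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric tube phantom.

    Semi-axes and twist are linear profiles along normalized arc length
    s in [0, 1]; ``landing_s`` marks the cross-section designated as the
    landing zone.  ``tangential_pose`` fixes the phantom's orientation:
    the landing section's plane contains that pose's beam and its major
    axis is perpendicular to it, so that pose is the ideal working view.
    """

    centerline: str = "straight"          # "straight" or "arc"
    length_mm: float = 60.0
    arc_radius_mm: float = 80.0           # used for centerline="arc"
    semi_axis_a_mm: tuple[float, float] = (15.0, 15.0)   # major, at s=0 and s=1
    semi_axis_b_mm: tuple[float, float] = (10.0, 10.0)   # minor
    twist_deg: tuple[float, float] = (0.0, 0.0)
    circumferential_segments: int = 128
    longitudinal_segments: int = 64
    landing_s: float = 0.5
    tangential_pose: CArmPose = field(default_factory=lambda: DEFAULT_POSE)
    rng_seed: int = 0

    def __post_init__(self):
        if self.centerline not in ("straight", "arc"):
            raise ValueError(f"unknown centerline kind {self.centerline!r}")
        for pair, name in ((self.semi_axis_a_mm, "semi_axis_a_mm"),
                           (self.semi_axis_b_mm, "semi_axis_b_mm")):
            if min(pair) <= 0:
                raise ValueError(f"{name} must be positive everywhere")
        if self.circumferential_segments < 16 or self.longitudinal_segments < 16:
            raise ValueError("mesh resolution must be at least 16 x 16")
        if not (0.0 < self.landing_s < 1.0):
            raise ValueError("landing_s must be strictly inside (0, 1)")
        if self.length_mm <= 0:
            raise ValueError("length_mm must be positive")

    def semi_axes_at(self, s) -> tuple[np.ndarray, np.ndarray]:
        return (_lerp(*self.semi_axis_a_mm, s), _lerp(*self.semi_axis_b_mm, s))

    def twist_at(self, s) -> np.ndarray:
        return np.radians(_lerp(*self.twist_deg, s))


@dataclass(frozen=True)
class GroundTruth:
    """Analytic truth at the landing-zone cross-section (never mesh-derived)."""

    plane_point: np.ndarray
    plane_normal: np.ndarray
    dmax_direction: np.ndarray
    endpoint_a: np.ndarray
    endpoint_b: np.ndarray
    d_max_mm: float
    d_min_mm: float
    area_mm2: float
    perimeter_mm: float
    d_peri_mm: float
    d_area_mm: float
    ovality_mm: float
    tangential_pose: CArmPose


def _ellipse_perimeter(a: float, b: float) -> float:
    """Exact ellipse perimeter via the complete elliptic integral E."""
    a, b = max(a, b), min(a, b)
    return 4.0 * a * float(ellipe(1.0 - (b / a) ** 2))


def _phantom_frames(spec: PhantomSpec, s: np.ndarray):
    """Centerline points and orthonormal section frames (e1, e2, tangent).

    The frames are anchored so that at ``landing_s`` (before twist) e1 is
    the major-axis direction perpendicular to the tangential beam and e2
    equals the beam itself; a straight tube keeps this frame everywhere,
    an arc rotates it with the centerline (e2 = arc-plane normal = beam).
    """
    v = viewing_direction(spec.tangential_pose)
    # deterministic major-axis direction perpendicular to the beam
    helper = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    d = np.cross(helper, v)
    d /= np.linalg.norm(d)
    axis = np.cross(d, v)  # tube tangent at the landing section

    if spec.centerline == "straight":
        t = (s - spec.landing_s) * spec.length_mm
        centers = np.outer(t, axis)
        e1 = np.tile(d, (len(s), 1))
        e2 = np.tile(v, (len(s), 1))
        tangents = np.tile(axis, (len(s), 1))
        return centers, e1, e2, tangents

    r = spec.arc_radius_mm
    if r <= max(max(spec.semi_axis_a_mm), max(spec.semi_axis_b_mm)):
        raise ValueError("arc radius must exceed the largest semi-axis (self-intersection)")
    theta = (s - spec.landing_s) * spec.length_mm / r
    # local frame: radial x, tangent y, arc normal z; landing point at local origin
    local = np.column_stack([r * np.cos(theta) - r, r * np.sin(theta), np.zeros_like(theta)])
    m = np.column_stack([d, axis, v])  # local x,y,z -> world d, axis, v
    centers = local @ m.T
    e1_local = np.column_stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)])
    tan_local = np.column_stack([-np.sin(theta), np.cos(theta), np.zeros_like(theta)])
    e1 = e1_local @ m.T
    tangents = tan_local @ m.T
    e2 = np.tile(v, (len(s), 1))
    return centers, e1, e2, tangents


def _ground_truth(spec: PhantomSpec) -> GroundTruth:
    s = np.array([spec.landing_s])
    centers, e1, e2, tangents = _phantom_frames(spec, s)
    c, e1, e2, n = centers[0], e1[0], e2[0], tangents[0]
    a, b = (float(x) for x in spec.semi_axes_at(spec.landing_s))
    tw = float(spec.twist_at(spec.landing_s))
    d_dir = math.cos(tw) * e1 + math.sin(tw) * e2
    b_dir = -math.sin(tw) * e1 + math.cos(tw) * e2
    if b > a:  # minor profile crossed over the major one
        d_dir, b_dir, a, b = b_dir, d_dir, b, a
    peri = _ellipse_perimeter(a, b)
    pose = optimal_angulation(n, d_dir).chosen
    return GroundTruth(
        plane_point=c,
        plane_normal=n,
        dmax_direction=d_dir,
        endpoint_a=c - a * d_dir,
        endpoint_b=c + a * d_dir,
        d_max_mm=2.0 * a,
        d_min_mm=2.0 * b,
        area_mm2=math.pi * a * b,
        perimeter_mm=peri,
        d_peri_mm=peri / math.pi,
        d_area_mm=2.0 * math.sqrt(a * b),
        ovality_mm=2.0 * (a - b),
        tangential_pose=pose,
    )


def generate_mesh(spec: PhantomSpec) -> tuple[SurfaceMesh, GroundTruth]:
    """Build the watertight swept-ellipse tube mesh and its ground truth.

    The sweep places ``longitudinal_segments + 1`` elliptical rings of
    ``circumferential_segments`` vertices along the centerline and caps
    both ends with triangle fans.  Output is deterministic for a given
    spec.
    """
    nl = spec.longitudinal_segments
    nc = spec.circumferential_segments
    s = np.linspace(0.0, 1.0, nl + 1)
    centers, e1, e2, _ = _phantom_frames(spec, s)
    a, b = spec.semi_axes_at(s)
    tw = spec.twist_at(s)
    phi = np.linspace(0.0, 2.0 * math.pi, nc, endpoint=False)

    cos_t, sin_t = np.cos(tw)[:, None], np.sin(tw)[:, None]
    e1r = cos_t * e1 + sin_t * e2
    e2r = -sin_t * e1 + cos_t * e2
    ring = (
        centers[:, None, :]
        + (a[:, None] * np.cos(phi)[None, :])[:, :, None] * e1r[:, None, :]
        + (b[:, None] * np.sin(phi)[None, :])[:, :, None] * e2r[:, None, :]
    )
    verts = ring.reshape(-1, 3)

    faces = []
    for j in range(nl):
        base0, base1 = j * nc, (j + 1) * nc
        for i in range(nc):
            i2 = (i + 1) % nc
            faces.append([base0 + i, base1 + i, base0 + i2])
            faces.append([base0 + i2, base1 + i, base1 + i2])
    # end caps: fan around the ring centers (outward-consistent winding)
    c0 = len(verts)
    verts = np.vstack([verts, centers[0], centers[-1]])
    c1 = c0 + 1
    last = nl * nc
    for i in range(nc):
        i2 = (i + 1) % nc
        faces.append([c0, i2, i])
        faces.append([c1, last + i, last + i2])

    mesh = SurfaceMesh(verts, np.asarray(faces, dtype=np.int64))
    if not mesh.is_watertight:  # pragma: no cover - construction guarantees it
        warnings.warn("generated phantom mesh is unexpectedly not watertight")
    return mesh, _ground_truth(spec)


def voxelize(mesh: SurfaceMesh, spacing_mm: float = 1.3, pad_mm: float = 10.0) -> ImageVolume:
    """Binary occupancy volume by center-of-voxel inside testing.

    The grid covers the mesh bounding box padded by ``pad_mm``, axes
    aligned with the patient frame.  Insideness is decided per (x, y)
    column by ray-crossing parity along z, which requires a watertight
    surface.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    if len(mesh.faces) == 0:
        raise ValueError("cannot voxelize an empty mesh")
    if not mesh.is_watertight:
        raise ValueError("voxelization requires a watertight mesh")
    lo = mesh.vertices.min(axis=0) - pad_mm
    hi = mesh.vertices.max(axis=0) + pad_mm
    shape = np.maximum(np.ceil((hi - lo) / spacing_mm).astype(int), 1)
    origin = lo + spacing_mm / 2.0

    xs = origin[0] + spacing_mm * np.arange(shape[0])
    ys = origin[1] + spacing_mm * np.arange(shape[1])
    zs = origin[2] + spacing_mm * np.arange(shape[2])

    data = np.zeros(shape, dtype=np.uint8)
    z0 = lo[2] - 1.0
    dirz = np.array([0.0, 0.0, 1.0])
    for ix, x in enumerate(xs):
        for iy, y in enumerate(ys):
            hits = intersect_ray_mesh(mesh, Ray(np.array([x, y, z0]), dirz))
            if len(hits) == 0:
                continue
            zhit = hits[:, 2]
            if len(zhit) % 2 == 1:
                zhit = zhit[:-1]  # grazing contact; drop the unpaired hit
            for z_in, z_out in zip(zhit[0::2], zhit[1::2]):
                data[ix, iy, (zs >= z_in) & (zs <= z_out)] = 1
    return ImageVolume(data=data, spacing=np.full(3, float(spacing_mm)),
                       origin=origin, direction=np.eye(3))


def simulate_annotation(
    spec: PhantomSpec,
    truth: GroundTruth,
    pose: CArmPose,
    endpoint_noise_mm: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize the periprocedural 2D diameter annotation.

    Projects the two true maximal-diameter wall points onto the detector
    under ``pose`` and adds isotropic Gaussian jitter of the stated
    standard deviation (the reader's marking imprecision).  Deterministic
    for a given seed.
    """
    q_a = project_point(pose, truth.endpoint_a)
    q_b = project_point(pose, truth.endpoint_b)
    if endpoint_noise_mm > 0:
        rng = np.random.default_rng(spec.rng_seed if seed is None else seed)
        q_a = q_a + rng.normal(0.0, endpoint_noise_mm, 2)
        q_b = q_b + rng.normal(0.0, endpoint_noise_mm, 2)
    return q_a, q_b


def phantom_family(n_cases: int, seed: int, base: PhantomSpec | None = None,
                   mean_dmax_mm: float = 22.0, subject_sd_mm: float = 3.0,
                   ovality_range: tuple[float, float] = (2.0, 8.0)) -> list[PhantomSpec]:
    """Draw a cohort of phantom specs with varying size and ovality.

    Major diameters are Gaussian around ``mean_dmax_mm`` (clipped to
    12 mm, the smallest clinically plausible landing zone); ovality is
    uniform over ``ovality_range`` — oval appendages are common and
    drive the divergence between the diameter definitions.  The lower
    ovality bound stays away from zero because a circular section has no
    defined major-axis direction: its optimal angulation is degenerate
    (any edge-on beam works), which would make angulation recovery
    meaningless rather than hard.
    """
    if n_cases < 2:
        raise ValueError("need at least 2 cases")
    rng = np.random.default_rng(seed)
    base = base or PhantomSpec()
    specs = []
    for i in range(n_cases):
        d_max = max(12.0, rng.normal(mean_dmax_mm, subject_sd_mm))
        oval = rng.uniform(*ovality_range)
        a = d_max / 2.0
        b = max(4.0, (d_max - oval) / 2.0)
        specs.append(replace(base, semi_axis_a_mm=(a, a), semi_axis_b_mm=(b, b),
                             rng_seed=seed + i + 1))
    return specs


def simulate_reader_panel(
    truths,
    n_readers: int = 3,
    reader_bias_mm: float = 0.0,
    reader_noise_mm: float = 0.0,
    modality_bias_mm: float = 0.0,
    modality_noise_mm: float = 0.0,
    seed: int = 0,
) -> tuple[RatingsMatrix, PairedMeasurements]:
    """Emulate multi-reader ratings and a second measurement modality.

    ``truths`` is a list of GroundTruth (or a list of true diameters in
    mm).  Each reader reports truth + a per-reader systematic offset
    (drawn once per reader around ``reader_bias_mm``) + Gaussian noise;
    the second modality reports truth + ``modality_bias_mm`` + noise
    (negative bias emulates the systematic underestimation of projective
    and echo measurements relative to tomographic sizing).  Returns the
    ratings matrix for reliability analysis and the truth-vs-modality
    pairs for agreement analysis.
    """
    d_true = np.array(
        [t.d_max_mm if isinstance(t, GroundTruth) else float(t) for t in truths]
    )
    if len(d_true) < 2:
        raise ValueError("need at least 2 cases")
    if min(n_readers, 2) < 2:
        raise ValueError("need at least 2 readers")
    if reader_noise_mm < 0 or modality_noise_mm < 0:
        raise ValueError("noise levels must be non-negative")
    rng = np.random.default_rng(seed)
    reader_offsets = (
        rng.normal(0.0, abs(reader_bias_mm), n_readers) if reader_bias_mm else np.zeros(n_readers)
    )
    ratings = (
        d_true[:, None]
        + reader_offsets[None, :]
        + rng.normal(0.0, reader_noise_mm, (len(d_true), n_readers))
    )
    modality = d_true + modality_bias_mm + rng.normal(0.0, modality_noise_mm, len(d_true))
    rm = RatingsMatrix(ratings, subject_ids=list(range(len(d_true))),
                       rater_ids=[f"reader{j + 1}" for j in range(n_readers)])
    pm = PairedMeasurements(
        case_ids=list(range(len(d_true))),
        values_a=modality,
        values_b=d_true,
        label_a="modality",
        label_b="truth",
    )
    return rm, pm
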