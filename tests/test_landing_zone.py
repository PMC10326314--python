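"""Landing-zone localization, cross-section measurement, and MPR."""

import math

import numpy as np
import pytest

from laaplan import (
    CArmPose,
    ImageVolume,
    PhantomSpec,
    SurfaceMesh,
    generate_mesh,
    landing_plane,
    localize_landing_zone,
    measure_cross_section,
    mpr_resample,
    polygon_max_diameter,
    projected_diameter,
    simulate_annotation,
    sizing_from_section,
    viewing_direction,
    voxelize,
)


# --- landing plane ---------------------------------------------------------

def test_landing_plane_cross_product():
    point, normal = landing_plane([0, 0, 0], [20, 0, 0], [0, 0, 1])
    np.testing.assert_allclose(point, [10, 0, 0])
    assert abs(normal @ np.array([0, 1, 0])) == pytest.approx(1.0)


def test_landing_plane_degenerate_inputs():
    with pytest.raises(ValueError, match="coincide"):
        landing_plane([1, 2, 3], [1, 2, 3], [0, 0, 1])
    with pytest.raises(ValueError, match="parallel"):
        landing_plane([0, 0, 0], [0, 0, 5], [0, 0, 1])


def test_landing_plane_matches_anatomy_on_tangential_view(ellipse_phantom):
    """An ideal edge-on annotation reconstructs the true section plane."""
    _, mesh, truth = ellipse_phantom
    v = viewing_direction(truth.tangential_pose)
    _, normal = landing_plane(truth.endpoint_a, truth.endpoint_b, v)
    angle = math.degrees(math.acos(min(1.0, abs(normal @ truth.plane_normal))))
    assert angle < 1.0


# --- localization ----------------------------------------------------------

def test_localization_roundtrip_noiseless(ellipse_phantom):
    spec, mesh, truth = ellipse_phantom
    pose = truth.tangential_pose
    qa, qb = simulate_annotation(spec, truth, pose)
    zone = localize_landing_zone(mesh, pose, qa, qb)
    assert np.linalg.norm(zone.endpoint_a - truth.endpoint_a) < 1.3
    assert np.linalg.norm(zone.endpoint_b - truth.endpoint_b) < 1.3
    angle = math.degrees(math.acos(min(1.0, abs(zone.plane_normal @ truth.plane_normal))))
    assert angle < 5.0


def test_localization_tangential_equal_depth(ellipse_phantom):
    """Grazing rays on opposite walls select a pair at matching depth."""
    spec, mesh, truth = ellipse_phantom
    pose = truth.tangential_pose
    qa, qb = simulate_annotation(spec, truth, pose)
    zone = localize_landing_zone(mesh, pose, qa, qb)
    v = viewing_direction(pose)
    assert abs((zone.endpoint_a - zone.endpoint_b) @ v) < 1e-6


def test_localization_names_missing_ray(ellipse_phantom):
    spec, mesh, truth = ellipse_phantom
    pose = truth.tangential_pose
    qa, qb = simulate_annotation(spec, truth, pose)
    with pytest.raises(ValueError, match="ray A misses mesh"):
        localize_landing_zone(mesh, pose, qa + 500.0, qb)
    with pytest.raises(ValueError, match="ray B misses mesh"):
        localize_landing_zone(mesh, pose, qa, qb + 500.0)


def test_localization_across_seeded_phantom_cohort():
    rng = np.random.default_rng(21)
    for i in range(5):
        a = rng.uniform(10, 16)
        b = rng.uniform(7, a)
        spec = PhantomSpec(semi_axis_a_mm=(a, a), semi_axis_b_mm=(b, b),
                           rng_seed=100 + i)
        mesh, truth = generate_mesh(spec)
        qa, qb = simulate_annotation(spec, truth, truth.tangential_pose)
        zone = localize_landing_zone(mesh, truth.tangential_pose, qa, qb)
        assert np.linalg.norm(zone.endpoint_a - truth.endpoint_a) < 1.3
        assert np.linalg.norm(zone.endpoint_b - truth.endpoint_b) < 1.3


# --- cross-section measurement --------------------------------------------

def test_measure_cross_section_selects_anatomical_loop(ellipse_phantom):
    spec, mesh, truth = ellipse_phantom
    qa, qb = simulate_annotation(spec, truth, truth.tangential_pose)
    zone = localize_landing_zone(mesh, truth.tangential_pose, qa, qb)
    sec = measure_cross_section(mesh, zone)
    rep = sizing_from_section(sec)
    assert rep.d_max_mm == pytest.approx(truth.d_max_mm, rel=0.05)
    assert rep.d_min_mm == pytest.approx(truth.d_min_mm, rel=0.05)


def test_measure_cross_section_prefers_nearest_loop():
    """With two lobes in the cut, the loop nearest the midpoint wins even
    when it encloses less area."""
    from laaplan.landing_zone import LandingZone
    from laaplan.mesh_ops import polygon_area

    small = PhantomSpec(semi_axis_a_mm=(6.0, 6.0), semi_axis_b_mm=(6.0, 6.0))
    big = PhantomSpec(semi_axis_a_mm=(14.0, 14.0), semi_axis_b_mm=(14.0, 14.0))
    m1, t1 = generate_mesh(small)
    m2, _ = generate_mesh(big)
    offset = np.array([60.0, 0.0, 0.0])
    verts = np.vstack([m1.vertices, m2.vertices + offset])
    faces = np.vstack([m1.faces, m2.faces + len(m1.vertices)])
    both = SurfaceMesh(verts, faces)
    zone = LandingZone(t1.endpoint_a, t1.endpoint_b, t1.plane_point,
                       t1.plane_normal, t1.tangential_pose)
    sec = measure_cross_section(both, zone)
    areas = [polygon_area(p) for p in sec.polygons]
    assert len(areas) >= 2
    assert areas[0] < max(areas)  # the selected loop is the small nearby one
    assert polygon_max_diameter(sec.polygons[0])[0] == pytest.approx(12.0, rel=0.01)


# --- projected diameter ----------------------------------------------------

def test_projected_diameter_unforeshortened_edge_on(ellipse_phantom):
    spec, mesh, truth = ellipse_phantom
    qa, qb = simulate_annotation(spec, truth, truth.tangential_pose)
    zone = localize_landing_zone(mesh, truth.tangential_pose, qa, qb)
    sec = measure_cross_section(mesh, zone)
    d_proj = projected_diameter(sec, truth.tangential_pose)
    d_max, _ = polygon_max_diameter(sec.polygons[0])
    assert d_proj == pytest.approx(d_max, rel=1e-6)


def test_projected_diameter_brute_force_oracle(ellipse_phantom):
    """Max pairwise distance of explicitly projected vertices."""
    spec, mesh, truth = ellipse_phantom
    qa, qb = simulate_annotation(spec, truth, truth.tangential_pose)
    zone = localize_landing_zone(mesh, truth.tangential_pose, qa, qb)
    sec = measure_cross_section(mesh, zone)
    for pose in [CArmPose(alpha_deg=10, beta_deg=-40), CArmPose(alpha_deg=-70, beta_deg=5)]:
        v = viewing_direction(pose)
        pts = sec.loop_points_3d(0)
        proj = pts - np.outer(pts @ v, v)
        brute = max(
            np.linalg.norm(proj[i] - proj[j])
            for i in range(0, len(proj), 4)
            for j in range(i, len(proj), 4)
        )
        assert projected_diameter(sec, pose) >= brute - 1e-9
        assert projected_diameter(sec, pose) <= polygon_max_diameter(sec.polygons[0])[0] + 1e-9


def test_projected_diameter_along_major_axis_shows_minor(ellipse_phantom):
    """Viewing down the 30 mm axis of a 30 x 20 ellipse reads 20 mm."""
    spec, mesh, truth = ellipse_phantom
    qa, qb = simulate_annotation(spec, truth, truth.tangential_pose)
    zone = localize_landing_zone(mesh, truth.tangential_pose, qa, qb)
    sec = measure_cross_section(mesh, zone)
    from laaplan import pose_from_direction

    pose = pose_from_direction(truth.dmax_direction)
    assert projected_diameter(sec, pose) == pytest.approx(truth.d_min_mm, rel=0.01)


# --- MPR -------------------------------------------------------------------

def _linear_volume():
    ii, jj, kk = np.meshgrid(np.arange(24), np.arange(24), np.arange(24), indexing="ij")
    data = 2.0 * ii - 1.5 * jj + 0.5 * kk + 3.0
    return ImageVolume(data, spacing=[1, 1, 1], origin=[0, 0, 0], direction=np.eye(3))


def test_mpr_reproduces_affine_field_exactly():
    vol = _linear_volume()
    point = np.array([11.5, 11.5, 11.5])
    a0 = np.array([1.0, 1.0, 0.0]) / math.sqrt(2)
    a1 = np.array([0.0, 0.0, 1.0])
    img = mpr_resample(vol, point, (a0, a1), fov_mm=8, spacing_mm=1.0)
    n = img.data.shape[0]
    for r in range(n):
        for c in range(n):
            world = img.pixel_to_world((r, c))
            expect = 2.0 * world[0] - 1.5 * world[1] + 0.5 * world[2] + 3.0
            assert img.data[r, c] == pytest.approx(expect, abs=1e-9)


def test_mpr_axis_aligned_constant_plane():
    ii = np.meshgrid(np.arange(16), np.arange(16), np.arange(16), indexing="ij")[2]
    vol = ImageVolume(ii.astype(float), [1, 1, 1], [0, 0, 0], np.eye(3))
    img = mpr_resample(vol, [7.5, 7.5, 5.0], ([1, 0, 0], [0, 1, 0]), fov_mm=8, spacing_mm=1)
    np.testing.assert_allclose(img.data, 5.0, atol=1e-12)


def test_mpr_outside_volume_is_fill():
    vol = _linear_volume()
    img = mpr_resample(vol, [500.0, 0, 0], ([1, 0, 0], [0, 1, 0]), fov_mm=5,
                       spacing_mm=1, fill_value=-7.0)
    np.testing.assert_array_equal(img.data, -7.0)


def test_mpr_sphere_disc_diameter(sphere_r10):
    """Thresholded MPR of a voxelized sphere shows a disc of diameter 2r."""
    vol = voxelize(sphere_r10, spacing_mm=1.0)
    img = mpr_resample(vol, [0.0, 0.0, 0.0], ([1, 0, 0], [0, 1, 0]),
                       fov_mm=30, spacing_mm=0.5)
    mask = img.data >= 0.5
    cols = np.where(mask.any(axis=0))[0]
    width_mm = (cols.max() - cols.min()) * 0.5
    assert width_mm == pytest.approx(20.0, abs=2.0)


def test_mpr_rejects_bad_frame():
    vol = _linear_volume()
    with pytest.raises(ValueError, match="orthogonal"):
        mpr_resample(vol, [0, 0, 0], ([1, 0, 0], [1, 0, 0]))
    with pytest.raises(ValueError, match="spacing"):
        mpr_resample(vol, [0, 0, 0], ([1, 0, 0], [0, 1, 0]), spacing_mm=0)


def test_nifti_roundtrip(tmp_path):
    rng = np.random.default_rng(31)
    vol = ImageVolume(rng.normal(size=(8, 9, 10)), spacing=[1.3, 1.3, 1.3],
                      origin=[-10.0, 4.0, 2.5], direction=np.eye(3))
    path = tmp_path / "v.nii.gz"
    vol.to_nifti(path)
    back = ImageVolume.from_nifti(path)
    np.testing.assert_allclose(back.data, vol.data, atol=1e-6)
    np.testing.assert_allclose(back.spacing, vol.spacing, atol=1e-6)
    np.testing.assert_allclose(back.origin, vol.origin, atol=1e-5)
    np.testing.assert_allclose(back.direction, vol.direction, atol=1e-6)
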