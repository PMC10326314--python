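import numpy as np
import pytest
import trimesh

from laaplan import PhantomSpec, SurfaceMesh, generate_mesh


def random_convex_polygon(rng, n_points=30, scale=20.0):
    """Convex hull of random points, as a CCW 2D loop."""
    from scipy.spatial import ConvexHull

    pts = rng.normal(0.0, scale, (n_points, 2))
    hull = ConvexHull(pts)
    return pts[hull.vertices]


@pytest.fixture(scope="session")
def icosphere():
    """Unit-radius triangulated sphere (analytic intersection oracle)."""
    sph = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    return SurfaceMesh(np.asarray(sph.vertices), np.asarray(sph.faces))


@pytest.fixture(scope="session")
def sphere_r10():
    sph = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
    return SurfaceMesh(np.asarray(sph.vertices), np.asarray(sph.faces))


@pytest.fixture(scope="session")
def ellipse_phantom():
    """Default straight elliptical tube (a=15, b=10) with ground truth."""
    spec = PhantomSpec()
    mesh, truth = generate_mesh(spec)
    return spec, mesh, truth


@pytest.fixture(scope="session")
def circle_phantom_512():
    """Circular tube of radius 10 at high circumferential resolution."""
    spec = PhantomSpec(
        semi_axis_a_mm=(10.0, 10.0),
        semi_axis_b_mm=(10.0, 10.0),
        circumferential_segments=512,
    )
    mesh, truth = generate_mesh(spec)
    return spec, mesh, truth
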