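import numpy as np
import pytest
import trimesh

from gyrosim.geometry import GeometrySpec, Invagination, generate_brain_proxy
from gyrosim.morphometrics import (
    SurfaceGeometry,
    angle_defect_total,
    count_folds,
    extract_surface,
    gyrification_index,
    principal_curvatures,
    shape_index,
    sulcal_depth,
)


def icosphere_surface(subdiv=4, radius=1.0):
    ico = trimesh.creation.icosphere(subdivisions=subdiv, radius=radius)
    return SurfaceGeometry(np.asarray(ico.vertices), np.asarray(ico.faces))


@pytest.fixture(scope="module")
def sphere_surface():
    return icosphere_surface()


@pytest.fixture(scope="module")
def dented_surface():
    """Sphere with one deep invagination (known groove fixture)."""
    spec = GeometrySpec(
        cortical_thickness=0.2,
        target_edge_length=0.1,
        noise_amplitude=0.0,
        invaginations=(Invagination((0, 0, 1), 0.4, 0.45),),
    )
    mesh = generate_brain_proxy(spec)
    return extract_surface(mesh.nodes, mesh)


class TestExtractSurface:
    def test_sphere_volume_and_orientation(self, sphere_mesh):
        surf = extract_surface(sphere_mesh.nodes, sphere_mesh)
        assert surf.enclosed_volume() > 0
        assert abs(surf.enclosed_volume() - 4 * np.pi / 3) / (4 * np.pi / 3) < 0.02
        assert surf.n_vertices == len(np.unique(sphere_mesh.boundary_tris))


class TestCurvature:
    def test_unit_sphere(self, sphere_surface):
        k1, k2 = principal_curvatures(sphere_surface)
        assert np.abs(k1 - 1.0).max() < 0.05
        assert np.abs(k2 - 1.0).max() < 0.05
        assert np.all(k1 >= k2)

    def test_radius_two_sphere_scaling(self):
        surf = icosphere_surface(radius=2.0)
        k1, k2 = principal_curvatures(surf)
        assert np.abs(k1 - 0.5).max() < 0.05 * 0.5
        assert np.abs(k2 - 0.5).max() < 0.05 * 0.5

    def test_cylinder_side_patch(self):
        # closed unit-radius cylinder with well-resolved side rings; evaluate
        # away from the cap rims where the crease dominates
        m, nz, h = 64, 24, 4.0
        ang = 2 * np.pi * np.arange(m) / m
        ring = np.column_stack([np.cos(ang), np.sin(ang)])
        verts = [np.column_stack([ring, np.full(m, z)]) for z in np.linspace(0, h, nz + 1)]
        verts = np.vstack(verts + [np.array([[0, 0, 0.0], [0, 0, h]])])
        bot_c, top_c = len(verts) - 2, len(verts) - 1
        tris = []
        for k in range(nz):
            a = k * m + np.arange(m)
            b = k * m + (np.arange(m) + 1) % m
            tris += list(zip(a, b, a + m)) + list(zip(b, b + m, a + m))
        tris += [(int((i + 1) % m), int(i), bot_c) for i in range(m)]
        tris += [(int(nz * m + i), int(nz * m + (i + 1) % m), top_c) for i in range(m)]
        surf = SurfaceGeometry(verts, np.asarray(tris, dtype=np.int64))
        k1, k2 = principal_curvatures(surf)
        mid = np.abs(surf.vertices[:, 2] - h / 2) < h / 4
        assert np.abs(k1[mid] - 1.0).max() < 0.1
        assert np.abs(k2[mid]).max() < 0.1

    def test_gauss_bonnet_closed_surfaces(self, sphere_surface, dented_surface):
        for surf in (sphere_surface, dented_surface):
            total = angle_defect_total(surf)
            assert abs(total - 4 * np.pi) / (4 * np.pi) < 1e-6


class TestShapeIndex:
    def test_worked_values(self):
        assert shape_index(np.array([1.0]), np.array([-1.0]))[0] == pytest.approx(0.0)
        assert shape_index(np.array([1.0]), np.array([0.0]))[0] == pytest.approx(0.5)
        assert shape_index(np.array([0.0]), np.array([-1.0]))[0] == pytest.approx(-0.5)

    def test_umbilic_conventions(self):
        # convex dome -> +1; concave pit -> -1; flat -> 0 by convention
        assert shape_index(np.array([2.0]), np.array([2.0]))[0] == 1.0
        assert shape_index(np.array([-2.0]), np.array([-2.0]))[0] == -1.0
        assert shape_index(np.array([0.0]), np.array([0.0]))[0] == 0.0

    def test_sphere_is_dome_everywhere(self, sphere_surface):
        k1, k2 = principal_curvatures(sphere_surface)
        s = shape_index(k1, k2)
        assert np.all(s > 0.9)

    def test_range(self, dented_surface):
        k1, k2 = principal_curvatures(dented_surface)
        s = shape_index(k1, k2)
        assert s.min() >= -1.0 and s.max() <= 1.0


class TestGyrificationIndex:
    def test_sphere_is_one(self, sphere_surface):
        assert gyrification_index(sphere_surface) == pytest.approx(1.0, abs=0.01)

    def test_convex_polyhedron_is_one(self):
        box = trimesh.creation.box()
        surf = SurfaceGeometry(np.asarray(box.vertices), np.asarray(box.faces))
        assert gyrification_index(surf) == pytest.approx(1.0, abs=1e-6)

    def test_deep_invagination_exceeds_one(self, dented_surface):
        # a single star-shaped (non-overhanging) dent adds ~1.5% area
        assert gyrification_index(dented_surface) > 1.01

    def test_multiply_invaginated_sphere(self):
        dirs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
        spec = GeometrySpec(
            cortical_thickness=0.2,
            target_edge_length=0.12,
            noise_amplitude=0.0,
            invaginations=tuple(Invagination(d, 0.45, 0.45) for d in dirs),
        )
        mesh = generate_brain_proxy(spec)
        surf = extract_surface(mesh.nodes, mesh)
        assert gyrification_index(surf) > 1.05
        assert count_folds(surf)[0] == 6

    def test_scale_invariance(self, dented_surface):
        scaled = SurfaceGeometry(3.0 * dented_surface.vertices, dented_surface.triangles)
        assert gyrification_index(scaled) == pytest.approx(
            gyrification_index(dented_surface), rel=1e-9
        )


class TestSulcalDepth:
    def test_convex_surface_zero(self, sphere_surface):
        assert sulcal_depth(sphere_surface).max() < 1e-6

    def test_depths_nonnegative(self, dented_surface):
        assert np.all(sulcal_depth(dented_surface) >= 0.0)

    def test_known_pit_depth(self, dented_surface):
        # cosine dent of depth 0.45 on the unit sphere; the hull spans the rim
        # chords, dipping by the spherical-cap sagitta 1 - cos(0.4), so the
        # deepest vertex sits at depth + cos(0.4) - 1 below the hull
        d = sulcal_depth(dented_surface)
        expected = 0.45 - (1.0 - np.cos(0.4))
        assert d.max() == pytest.approx(expected, rel=0.15)


class TestCountFolds:
    def test_smooth_ellipsoid_has_none(self):
        tm = trimesh.creation.icosphere(subdivisions=3)
        surf = SurfaceGeometry(np.asarray(tm.vertices) * [1.3, 1.0, 0.9], np.asarray(tm.faces))
        assert count_folds(surf)[0] == 0

    def test_two_disjoint_grooves(self):
        spec = GeometrySpec(
            cortical_thickness=0.2,
            target_edge_length=0.1,
            noise_amplitude=0.0,
            invaginations=(
                Invagination((0, 0, 1), 0.45, 0.3),
                Invagination((0, 0, -1), 0.45, 0.3),
            ),
        )
        mesh = generate_brain_proxy(spec)
        surf = extract_surface(mesh.nodes, mesh)
        count, labels = count_folds(surf)
        assert count == 2
        assert labels.max() == 1

    def test_rotation_invariance(self):
        from scipy.spatial.transform import Rotation

        spec = GeometrySpec(
            cortical_thickness=0.2,
            target_edge_length=0.1,
            noise_amplitude=0.0,
            invaginations=(Invagination((0, 1, 1), 0.45, 0.3),),
        )
        mesh = generate_brain_proxy(spec)
        surf = extract_surface(mesh.nodes, mesh)
        R = Rotation.from_rotvec([0.7, -0.4, 1.1]).as_matrix()
        rotated = SurfaceGeometry(surf.vertices @ R.T, surf.triangles)
        assert count_folds(rotated)[0] == count_folds(surf)[0]
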