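import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gyrosim.geometry import (
    GeometrySpec,
    Invagination,
    MeshingError,
    _brute_nearest,
    apply_thickness_modifier,
    build_cortical_field,
    check_watertight,
    compute_reference_depth,
    cortical_indicator,
    generate_brain_proxy,
    generate_flat_bilayer,
    mesh_digest,
)


class TestBrainProxy:
    def test_sphere_volume_and_watertightness(self, sphere_mesh):
        assert sphere_mesh.tet_volumes().min() > 0
        check_watertight(sphere_mesh)
        vol = sphere_mesh.volume()
        assert abs(vol - 4 * np.pi / 3) / (4 * np.pi / 3) < 0.02

    def test_determinism_bitwise(self, sphere_spec, sphere_mesh):
        again = generate_brain_proxy(sphere_spec)
        assert np.array_equal(again.nodes, sphere_mesh.nodes)
        assert np.array_equal(again.tets, sphere_mesh.tets)
        assert mesh_digest(again) == mesh_digest(sphere_mesh)

    def test_seed_changes_surface(self):
        spec = GeometrySpec(cortical_thickness=0.1, target_edge_length=0.25, seed=0)
        a = generate_brain_proxy(spec)
        b = generate_brain_proxy(GeometrySpec(cortical_thickness=0.1, target_edge_length=0.25, seed=1))
        assert not np.array_equal(a.nodes, b.nodes)

    def test_invagination_increases_area(self):
        base = GeometrySpec(
            cortical_thickness=0.2, target_edge_length=0.2, seed=0, noise_amplitude=0.0
        )
        dented = GeometrySpec(
            cortical_thickness=0.2,
            target_edge_length=0.2,
            seed=0,
            noise_amplitude=0.0,
            invaginations=(Invagination((0, 0, 1), 0.4, 0.3),),
        )
        area0 = generate_brain_proxy(base).surface_mesh().area
        area1 = generate_brain_proxy(dented).surface_mesh().area
        assert area1 > area0

    def test_element_count_scales_with_resolution(self):
        coarse = generate_brain_proxy(GeometrySpec(cortical_thickness=0.25, target_edge_length=0.3))
        fine = generate_brain_proxy(GeometrySpec(cortical_thickness=0.25, target_edge_length=0.15))
        assert fine.n_tets > 3 * coarse.n_tets

    def test_degenerate_spec_raises(self):
        with pytest.raises(MeshingError, match="cortical_thickness"):
            GeometrySpec(semi_axes=(1, 1, 1), cortical_thickness=1.5)
        with pytest.raises(MeshingError, match="semi_axes"):
            GeometrySpec(semi_axes=(1, -1, 1))
        with pytest.raises(MeshingError, match="depth_fraction"):
            Invagination((0, 0, 1), 0.5, 1.5)


class TestFlatBilayer:
    def test_box_volume_and_flags(self, small_slab):
        assert small_slab.n_nodes > 0
        assert abs(small_slab.volume() - 1.0) < 0.01
        # bottom face flagged for fixed boundary conditions
        assert len(small_slab.fixed_nodes) > 0
        assert np.allclose(small_slab.nodes[small_slab.fixed_nodes, 2], -1.0)

    def test_boundary_faces_axis_aligned(self, small_slab):
        from gyrosim.geometry import _triangle_normals

        n = _triangle_normals(small_slab.nodes, small_slab.boundary_tris)
        axis_aligned = np.isclose(np.abs(n), 1.0, atol=1e-9).any(axis=1)
        assert axis_aligned.all()

    def test_theta_volume_fraction_matches_quarter_thickness(self):
        slab = generate_flat_bilayer(2.0, 2.0, 1.0, 0.25, 0.1)
        from gyrosim.geometry import _triangle_normals

        tn = _triangle_normals(slab.nodes, slab.boundary_tris)
        fld = build_cortical_field(slab, 0.25, tris=slab.boundary_tris[tn[:, 2] > 0.5])
        vols = slab.tet_volumes()
        frac = vols[fld.theta > 0.5].sum() / vols.sum()
        assert abs(frac - 0.25) < 0.05

    def test_nonpositive_dimension_raises(self):
        with pytest.raises(MeshingError, match="depth"):
            generate_flat_bilayer(1.0, 1.0, -1.0, 0.25, 0.2)
        with pytest.raises(MeshingError, match="cortical_thickness"):
            generate_flat_bilayer(1.0, 1.0, 1.0, 2.0, 0.2)


class TestReferenceDepth:
    def test_agrees_with_exhaustive_brute_force(self, sphere_mesh):
        depth, _ = _brute_nearest(
            sphere_mesh.centroids(), sphere_mesh.nodes[sphere_mesh.boundary_tris]
        )
        fast = compute_reference_depth(sphere_mesh)
        assert np.abs(fast - depth).max() < 1e-10

    def test_boundary_point_depth_zero(self, sphere_mesh):
        surf_node = sphere_mesh.boundary_tris[0, 0]
        d = compute_reference_depth(sphere_mesh, sphere_mesh.nodes[[surf_node]])
        assert d[0] < 1e-12

    def test_sphere_max_depth(self, sphere_mesh, sphere_spec):
        depth = compute_reference_depth(sphere_mesh)
        assert depth.max() <= 1.0
        assert depth.max() >= 0.8 * (1.0 - sphere_spec.target_edge_length)

    def test_slab_depth_reaches_bottom(self, small_slab):
        # distance to the whole boundary, bottom face included
        depth = compute_reference_depth(small_slab)
        assert depth.max() <= 0.5 + 1e-9  # half the smallest box dimension
        assert depth.max() > 0.5 - 0.2


class TestCorticalIndicator:
    def test_printed_formula_values(self):
        T = 0.1
        assert cortical_indicator(np.array([T]), T)[0] == pytest.approx(0.5, abs=1e-12)
        assert cortical_indicator(np.array([0.0]), T)[0] == pytest.approx(
            1.0 / (1.0 + np.exp(-10.0)), abs=1e-12
        )
        assert cortical_indicator(np.array([10 * T]), T)[0] < 1e-38

    @given(
        y=st.floats(0.0, 5.0),
        dy=st.floats(0.001, 5.0),
        T=st.floats(0.01, 2.0),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_bounded_and_monotone_decreasing_in_depth(self, y, dy, T):
        t1, t2 = cortical_indicator(np.array([y, y + dy]), T)
        assert 0.0 <= t2 <= t1 <= 1.0
        if t1 > 1e-300:  # below this both saturate to zero in float64
            assert t2 < t1

    def test_nonpositive_thickness_raises(self):
        with pytest.raises(ValueError):
            cortical_indicator(np.array([0.1]), 0.0)


class TestThicknessModifier:
    def test_identity_factor(self, sphere_mesh, sphere_field):
        out = apply_thickness_modifier(sphere_mesh, sphere_field, 1.0)
        assert np.array_equal(out.thickness_T, sphere_field.thickness_T)
        assert np.allclose(out.theta, sphere_field.theta)

    def test_global_quarter_shrinks_cortex_fourfold(self):
        # resolve the thin cortex: use a slab with fine vertical resolution
        slab = generate_flat_bilayer(2.0, 2.0, 1.0, 0.4, 0.05)
        from gyrosim.geometry import _triangle_normals

        tn = _triangle_normals(slab.nodes, slab.boundary_tris)
        fld = build_cortical_field(slab, 0.4, tris=slab.boundary_tris[tn[:, 2] > 0.5])
        out = apply_thickness_modifier(slab, fld, 0.25)
        vols = slab.tet_volumes()
        before = vols[fld.theta > 0.5].sum()
        after = vols[out.theta > 0.5].sum()
        assert abs(after / before - 0.25) < 0.15 * 0.25 + 0.05

    def test_local_patch_leaves_far_field_unchanged(self, sphere_mesh, sphere_field):
        radius = 0.5
        out = apply_thickness_modifier(
            sphere_mesh, sphere_field, 0.25, region=((1.0, 0.0, 0.0), radius)
        )
        cent = sphere_mesh.centroids() - sphere_mesh.nodes.mean(axis=0)
        cent /= np.linalg.norm(cent, axis=1, keepdims=True)
        ang = np.arccos(np.clip(cent @ np.array([1.0, 0, 0]), -1, 1))
        far = ang > radius * 1.5 + 1e-6
        assert far.any()
        assert np.abs(out.theta[far] - sphere_field.theta[far]).max() < 1e-6
        inside = ang < radius
        assert np.allclose(out.thickness_T[inside], 0.25 * sphere_field.thickness_T[inside])

    def test_empty_region_raises(self, sphere_mesh, sphere_field):
        with pytest.raises(ValueError):
            apply_thickness_modifier(
                sphere_mesh, sphere_field, 0.25, region=((1.0, 0, 0), -1.0)
            )
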