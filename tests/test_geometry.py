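"""Ellipsoid geometry: implicit/parametric forms, volume, voxelization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from insulatk.geometry import EllipsoidModel, MaskVolume, make_ellipsoid


class TestConstruction:
    def test_reference_right_insula(self, right_insula):
        assert right_insula.center == (40.0, 5.0, 5.0)
        assert right_insula.semi_axes == (12.0, 8.0, 6.0)

    def test_reference_left_insula(self, left_insula):
        assert left_insula.center == (-40.0, 5.0, 5.0)
        assert left_insula.semi_axes == (12.0, 8.0, 6.0)

    @pytest.mark.parametrize(
        "axes", [(0.0, 8, 6), (-1.0, 8, 6), (12, 8, float("nan")), (12, float("inf"), 6)]
    )
    def test_degenerate_semi_axes_rejected(self, axes):
        with pytest.raises(ValueError):
            make_ellipsoid((0, 0, 0), axes)

    def test_nonfinite_center_rejected(self):
        with pytest.raises(ValueError):
            make_ellipsoid((float("nan"), 0, 0), (1, 1, 1))


class TestImplicitForm:
    @pytest.mark.parametrize(
        "point, expected",
        [
            ((40, 5, 5), 0.0),  # centre
            ((52, 5, 5), 1.0),  # surface at x0 + a
            ((40, 13, 5), 1.0),  # surface at y0 + b
            ((40, 5, 11), 1.0),  # surface at z0 + c
        ],
    )
    def test_right_insula_landmarks(self, right_insula, point, expected):
        assert right_insula.implicit_value(point) == pytest.approx(expected, abs=1e-12)

    def test_left_insula_face_coordinate(self, left_insula):
        # 0 + 441/64 + 36/36 by hand
        assert left_insula.implicit_value((-40, -16, 11)) == pytest.approx(7.890625, abs=1e-12)

    def test_containment_is_boundary_inclusive(self, right_insula):
        assert right_insula.contains((40, 5, 5))
        assert right_insula.contains((52, 5, 5))
        assert not right_insula.contains((52.001, 5, 5))

    def test_hand_coordinate_outside_left_insula(self, left_insula):
        # 0 + 576/64 + 81/36 = 11.25 > 1
        assert left_insula.implicit_value((-40, -19, 14)) == pytest.approx(11.25)
        assert not left_insula.contains((-40, -19, 14))

    def test_vectorized_points(self, right_insula):
        pts = np.array([[40, 5, 5], [52, 5, 5], [60, 5, 5]], dtype=float)
        np.testing.assert_allclose(right_insula.implicit_value(pts), [0, 1, 25 / 9])
        np.testing.assert_array_equal(right_insula.contains(pts), [True, True, False])


class TestParametricSurface:
    @pytest.mark.parametrize(
        "u, v, expected",
        [
            (0.0, math.pi / 2, (52, 5, 5)),  # +x pole
            (0.0, 0.0, (40, 5, 11)),  # +z pole, any u
            (1.0, 0.0, (40, 5, 11)),
            (math.pi / 2, math.pi / 2, (40, 13, 5)),  # +y extreme
        ],
    )
    def test_landmark_angles(self, right_insula, u, v, expected):
        np.testing.assert_allclose(right_insula.surface_point(u, v), expected, atol=1e-12)

    def test_random_angles_lie_on_surface(self, right_insula, rng):
        u = rng.uniform(0, 2 * np.pi, 1000)
        v = rng.uniform(0, np.pi, 1000)
        vals = right_insula.implicit_value(right_insula.surface_point(u, v))
        np.testing.assert_allclose(vals, 1.0, atol=1e-12)

    def test_surface_point_extremes_attain_bounding_box(self, right_insula):
        lo, hi = right_insula.bounding_box()
        attained = right_insula.surface_point(
            [0.0, np.pi, np.pi / 2, 3 * np.pi / 2, 0.0, 0.0],
            [np.pi / 2, np.pi / 2, np.pi / 2, np.pi / 2, 0.0, np.pi],
        )
        assert attained[:, 0].max() == pytest.approx(hi[0], abs=1e-9)
        assert attained[:, 0].min() == pytest.approx(lo[0], abs=1e-9)
        assert attained[:, 1].max() == pytest.approx(hi[1], abs=1e-9)
        assert attained[:, 1].min() == pytest.approx(lo[1], abs=1e-9)
        assert attained[:, 2].max() == pytest.approx(hi[2], abs=1e-9)
        assert attained[:, 2].min() == pytest.approx(lo[2], abs=1e-9)


class TestSurfaceMesh:
    def test_small_grid_vertex_count_and_surface(self, right_insula):
        mesh = right_insula.surface_mesh(nu=4, nv=3)
        assert mesh.n_vertices == 12
        vals = right_insula.implicit_value(mesh.vertices)
        np.testing.assert_allclose(vals, 1.0, atol=1e-9)

    @pytest.mark.parametrize("nu, nv", [(2, 3), (3, 2), (1, 1)])
    def test_too_small_grid_rejected(self, right_insula, nu, nv):
        with pytest.raises(ValueError):
            right_insula.surface_mesh(nu=nu, nv=nv)

    def test_max_vertex_distance_is_largest_semi_axis(self, right_insula):
        mesh = right_insula.surface_mesh(nu=16, nv=9)  # odd nv: equator row present
        d = np.linalg.norm(mesh.vertices - np.array(right_insula.center), axis=1)
        assert d.max() == pytest.approx(12.0, abs=1e-9)
        assert np.all(d <= 12.0 + 1e-9)

    def test_faces_reference_valid_vertices(self, right_insula):
        mesh = right_insula.surface_mesh(nu=8, nv=7)
        assert mesh.faces.min() >= 0
        assert mesh.faces.max() < mesh.n_vertices
        # every face has three geometrically distinct corners
        v = mesh.vertices[mesh.faces]
        for a, b in [(0, 1), (0, 2), (1, 2)]:
            assert np.linalg.norm(v[:, a] - v[:, b], axis=1).min() > 1e-9


class TestVolume:
    def test_closed_form(self, right_insula):
        assert right_insula.volume() == pytest.approx(768 * math.pi)

    def test_unit_sphere(self):
        assert make_ellipsoid((0, 0, 0), (1, 1, 1)).volume() == pytest.approx(4 * math.pi / 3)

    def test_scaling_law(self, right_insula):
        doubled = make_ellipsoid(right_insula.center, tuple(2 * s for s in right_insula.semi_axes))
        assert doubled.volume() == pytest.approx(8 * right_insula.volume())

    def test_monte_carlo_cross_check(self, right_insula, rng):
        lo, hi = right_insula.bounding_box()
        n = 1_000_000
        pts = rng.uniform(lo, hi, size=(n, 3))
        p = right_insula.contains(pts).mean()
        box = np.prod(hi - lo)
        se = box * np.sqrt(p * (1 - p) / n)
        assert abs(p * box - right_insula.volume()) < 3 * se


class TestExtentsAndMirror:
    def test_reference_extents(self, right_insula):
        assert right_insula.extents() == (24.0, 16.0, 12.0)

    def test_unit_sphere_extents(self):
        assert make_ellipsoid((0, 0, 0), (1, 1, 1)).extents() == (2.0, 2.0, 2.0)

    def test_bounding_box(self, right_insula):
        lo, hi = right_insula.bounding_box()
        np.testing.assert_allclose(lo, [28, -3, -1])
        np.testing.assert_allclose(hi, [52, 13, 11])

    def test_mirror_maps_right_to_left(self, right_insula, left_insula):
        assert right_insula.mirror_lr() == left_insula

    def test_mirror_is_involution(self, right_insula):
        assert right_insula.mirror_lr().mirror_lr() == right_insula

    @settings(max_examples=100, derandomize=True)
    @given(
        px=st.floats(-60, 60), py=st.floats(-30, 30), pz=st.floats(-30, 30),
    )
    def test_mirror_preserves_containment(self, px, py, pz):
        e = make_ellipsoid((40, 5, 5), (12, 8, 6))
        assert e.mirror_lr().contains((-px, py, pz)) == e.contains((px, py, pz))


class TestVoxelize:
    def test_voxel_volume_close_to_analytic_at_1mm(self, right_insula):
        mask = right_insula.voxelize(1.0)
        assert mask.volume() == pytest.approx(right_insula.volume(), rel=0.02)

    def test_finer_grid_tighter_agreement(self, right_insula):
        mask = right_insula.voxelize(0.5)
        assert mask.volume() == pytest.approx(right_insula.volume(), rel=0.005)

    def test_convergence_sequence(self, right_insula):
        errors = [
            abs(right_insula.voxelize(h).volume() - right_insula.volume()) / right_insula.volume()
            for h in (2.0, 1.0, 0.5)
        ]
        assert errors[0] > errors[1] > errors[2]

    def test_tiny_sphere_coarse_voxel_single_hit(self):
        mask = make_ellipsoid((0, 0, 0), (1, 1, 1)).voxelize(2.0)
        assert mask.n_inside == 1

    def test_affine_maps_indices_to_inside_points(self, right_insula):
        mask = right_insula.voxelize(2.0)
        world = mask.world_coordinates()
        inside = world[mask.data == 1]
        assert np.all(right_insula.contains(inside))
        outside = world[mask.data == 0]
        assert not np.any(right_insula.contains(outside))

    @pytest.mark.parametrize("h", [0.0, -1.0])
    def test_bad_voxel_size_rejected(self, right_insula, h):
        with pytest.raises(ValueError):
            right_insula.voxelize(h)

    def test_mask_volume_validation(self):
        with pytest.raises(ValueError):
            MaskVolume(data=np.full((2, 2, 2), 2), affine=np.eye(4), voxel_size=1.0)
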