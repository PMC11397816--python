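"""Workspace construction, prism inclusion and cloud filtering.

The trapezoidal half-space test is cross-checked against a convex-hull
membership oracle built by an entirely different construction
(scipy.spatial.ConvexHull facet equations).
"""

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from canopykit import (CameraIntrinsics, PickCycleSpec, PickMode,
                       FilterStrategy, backproject, project, cloud_from_mask,
                       filter_cloud, make_workspace, plane_from_points,
                       point_in_rect_prism, point_in_trap_prism)
from canopykit.geometry3d import PointCloud
from canopykit.synthetic import (LabeledScene, PrimitiveKind, ScenePrimitive,
                                 render)


def hull_membership(vertices, points, tol=1e-9):
    """Independent oracle: inside iff on the inner side of every hull facet.

    The boundary band (tol x point magnitude) matches the boundary-inside
    rule of the half-space test so the two classify identically.
    """
    hull = ConvexHull(vertices)
    vals = points @ hull.equations[:, :3].T + hull.equations[:, 3]
    scale = max(1.0, np.abs(points).max())
    return np.all(vals <= tol * scale, axis=1)


def random_spec(rng, mode=PickMode.MOVING, h2_equals_h1=False):
    home = rng.uniform([-500, -400, 300], [500, 400, 900])
    fruit = home + rng.uniform([-400, -300, 500], [400, 300, 1500])
    h1 = rng.uniform(40, 120)
    h2 = h1 if h2_equals_h1 else h1 + rng.uniform(0, 300)
    return PickCycleSpec(home=home, fruit=fruit, width=rng.uniform(50, 200),
                         height1=h1, height2=h2, mode=mode)


class TestBackprojection:
    def test_principal_point_maps_to_axis(self, K):
        np.testing.assert_allclose(backproject(K.cx, K.cy, 1000.0, K),
                                   [0.0, 0.0, 1000.0])

    def test_hand_computed_offset_pixel(self):
        K = CameraIntrinsics(fx=500, fy=500, cx=320, cy=240, width=841, height=480)
        np.testing.assert_allclose(backproject(820, 240, 1000.0, K),
                                   [1000.0, 0.0, 1000.0])

    def test_project_backproject_round_trip(self, K):
        rng = np.random.default_rng(0)
        u = rng.uniform(0, K.width - 1, 100)
        v = rng.uniform(0, K.height - 1, 100)
        d = rng.uniform(500, 4000, 100)
        uv = project(backproject(u, v, d, K), K)
        np.testing.assert_allclose(uv, np.stack([u, v], axis=-1), atol=1e-9)

    def test_invalid_depth_rejected(self, K):
        with pytest.raises(ValueError):
            backproject(10, 10, 0.0, K)


class TestCloudFromMask:
    def test_single_pixel_at_principal_point(self, K):
        mask = np.zeros((540, 640), dtype=bool)
        depth = np.zeros((540, 640))
        mask[270, 320] = True
        depth[270, 320] = 2000.0
        cloud = cloud_from_mask(mask, depth, K)
        np.testing.assert_allclose(cloud.points, [[0.0, 0.0, 2000.0]])

    def test_all_invalid_depth_counts_skips(self, K):
        mask = np.zeros((540, 640), dtype=bool)
        mask[:10, :10] = True
        cloud = cloud_from_mask(mask, np.zeros((540, 640)), K)
        assert len(cloud) == 0 and cloud.n_invalid_skipped == 100

    def test_resolution_mismatch_raises(self, K):
        with pytest.raises(ValueError, match="resolution"):
            cloud_from_mask(np.ones((10, 10), bool), np.ones((20, 20)), K)

    def test_branch_cloud_lies_on_cylinder_surface(self, K):
        # local z axis mapped to camera x: horizontal branch
        rot = np.column_stack([[0, 0, 1.0], [0, 1.0, 0], [1.0, 0, 0]])
        branch = ScenePrimitive(kind=PrimitiveKind.BRANCH_CYLINDER,
                                position=(0, 50, 1800), dims=(30.0, 2000.0),
                                instance_id=1, rotation=rot)
        scene = LabeledScene(primitives=(branch,), intrinsics=K,
                             resolution=(640, 540), seed=0)
        frame = render(scene, with_rgb=False)
        cloud = cloud_from_mask(frame.instance_map == 1, frame.depth, K)
        local = (cloud.points - branch.position) @ branch.rotation
        radial = np.sqrt(local[:, 0] ** 2 + local[:, 1] ** 2)
        # noiseless: every back-projected point sits on the lateral surface
        assert np.quantile(np.abs(radial - 30.0), 0.99) < 1e-3

    def test_ply_round_trip(self, K, tmp_path):
        pts = np.random.default_rng(1).uniform(-500, 500, (50, 3))
        PointCloud(points=pts).to_ply(tmp_path / "c.ply")
        back = PointCloud.from_ply(tmp_path / "c.ply")
        np.testing.assert_allclose(back.points, pts, atol=1e-4)


class TestPlaneFromPoints:
    def test_xy_plane(self):
        pl = plane_from_points((0, 0, 0), (1, 0, 0), (0, 1, 0))
        assert (pl.a, pl.b, pl.c, pl.d) == (0.0, 0.0, 1.0, 0.0)

    def test_normal_orthogonal_to_spanning_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            A, B, C = rng.uniform(-1000, 1000, (3, 3))
            try:
                pl = plane_from_points(A, B, C)
            except ValueError:
                continue
            n = pl.normal
            assert abs(n @ (B - A)) <= 1e-6 * np.linalg.norm(n)
            assert abs(n @ (C - A)) <= 1e-6 * np.linalg.norm(n)
            for P in (A, B, C):
                assert abs(pl.evaluate(P)[0]) <= 1e-6 * np.linalg.norm(n)

    def test_collinear_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            plane_from_points((0, 0, 0), (1, 1, 1), (2, 2, 2))


class TestMakeWorkspace:
    def test_stationary_axis_aligned_example(self):
        spec = PickCycleSpec(home=(0, 0, 500), fruit=(0, 0, 1500),
                             width=100, height1=80)
        prism = make_workspace(spec)
        lo, hi = prism.bounds()
        np.testing.assert_allclose(lo, [-50, -40, 500])
        np.testing.assert_allclose(hi, [50, 40, 1500])
        assert prism.is_axis_aligned_rect()

    def test_moving_with_equal_heights_degenerates_to_rect(self):
        stat = make_workspace(PickCycleSpec(home=(0, 0, 500), fruit=(100, 50, 1500),
                                            width=100, height1=80))
        trap = make_workspace(PickCycleSpec(home=(0, 0, 500), fruit=(100, 50, 1500),
                                            width=100, height1=80, height2=80,
                                            mode=PickMode.MOVING))
        np.testing.assert_allclose(stat.vertices, trap.vertices)

    def test_faces_planar_and_centroid_negative(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            prism = make_workspace(random_spec(rng))
            centroid = prism.centroid
            for quad, plane in zip(prism.faces, prism.planes):
                for vi in quad:  # all four face vertices on the plane
                    v = prism.vertices[vi]
                    assert abs(plane.evaluate(v)[0]) < 1e-6 * np.linalg.norm(plane.normal)
                assert plane.evaluate(centroid)[0] < 0

    def test_degenerate_and_invalid_specs(self):
        with pytest.raises(ValueError):
            PickCycleSpec(home=(0, 0, 500), fruit=(0, 0, 400), width=10, height1=10)
        with pytest.raises(ValueError, match="H2"):
            PickCycleSpec(home=(0, 0, 500), fruit=(0, 0, 900), width=10,
                          height1=50, height2=20, mode=PickMode.MOVING)


class TestPointInPrism:
    def test_centroid_and_outside_point(self):
        prism = make_workspace(PickCycleSpec(home=(0, 0, 500), fruit=(0, 0, 1500),
                                             width=100, height1=80))
        assert point_in_rect_prism(prism.centroid, prism)
        assert not point_in_rect_prism(prism.centroid + [51, 0, 0], prism)
        assert point_in_trap_prism(prism.centroid, prism)

    def test_vertices_count_as_inside(self):
        rng = np.random.default_rng(4)
        prism = make_workspace(random_spec(rng))
        assert point_in_trap_prism(prism.vertices, prism).all()

    def test_as_printed_mode_has_no_near_z_bound(self):
        prism = make_workspace(PickCycleSpec(home=(0, 0, 500), fruit=(0, 0, 1500),
                                             width=100, height1=80))
        in_front = np.array([0.0, 0.0, 100.0])  # nearer than the home plane
        assert not point_in_rect_prism(in_front, prism)
        assert point_in_rect_prism(in_front, prism, as_printed=True)
        beyond = np.array([0.0, 0.0, 1501.0])
        assert not point_in_rect_prism(beyond, prism, as_printed=True)

    def test_rect_test_rejects_oblique_prism(self):
        rng = np.random.default_rng(5)
        prism = make_workspace(random_spec(rng))
        with pytest.raises(ValueError, match="trapezoidal"):
            point_in_rect_prism(prism.centroid, prism)

    def test_trap_matches_convex_hull_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            prism = make_workspace(random_spec(rng))
            lo, hi = prism.bounds()
            pts = rng.uniform(lo - 100, hi + 100, (20000, 3))
            got = point_in_trap_prism(pts, prism)
            np.testing.assert_array_equal(got, hull_membership(prism.vertices, pts))

    def test_degenerate_trapezoid_matches_rect_test(self):
        rng = np.random.default_rng(7)
        spec = PickCycleSpec(home=(0, 0, 600), fruit=(0, 0, 1800),
                             width=120, height1=90, height2=90,
                             mode=PickMode.MOVING)
        prism = make_workspace(spec)
        lo, hi = prism.bounds()
        pts = rng.uniform(lo - 50, hi + 50, (20000, 3))
        np.testing.assert_array_equal(point_in_trap_prism(pts, prism),
                                      point_in_rect_prism(pts, prism))


class TestFilterCloud:
    def test_empty_cloud_not_obstructed(self):
        spec = PickCycleSpec(home=(0, 0, 500), fruit=(0, 0, 1500),
                             width=100, height1=80)
        result = filter_cloud(PointCloud(points=np.empty((0, 3))), spec)
        assert not result.obstructed and len(result.inside_indices) == 0

    @pytest.mark.parametrize("strategy", list(FilterStrategy))
    def test_centroid_point_obstructs_under_every_strategy(self, strategy):
        spec = PickCycleSpec(home=(0, 0, 500), fruit=(200, 100, 1500),
                             width=100, height1=80, height2=160,
                             mode=PickMode.MOVING)
        centroid = make_workspace(spec).centroid
        result = filter_cloud(PointCloud(points=centroid[None]), spec, strategy)
        assert result.obstructed

    @pytest.mark.parametrize("strategy", list(FilterStrategy))
    def test_partition_conservation(self, strategy):
        rng = np.random.default_rng(8)
        spec = random_spec(rng)
        cloud = PointCloud(points=rng.uniform([-800, -600, 200],
                                              [800, 600, 3000], (5000, 3)))
        result = filter_cloud(cloud, spec, strategy)
        union = np.sort(np.concatenate([result.inside_indices,
                                        result.outside_indices]))
        np.testing.assert_array_equal(union, np.arange(len(cloud)))

    def test_trap_after_rect_equals_trap_only(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            spec = random_spec(rng)
            cloud = PointCloud(points=rng.uniform([-800, -600, 200],
                                                  [800, 600, 3000], (5000, 3)))
            a = filter_cloud(cloud, spec, FilterStrategy.TRAP_AFTER_RECT)
            b = filter_cloud(cloud, spec, FilterStrategy.TRAP_ONLY)
            np.testing.assert_array_equal(np.sort(a.inside_indices),
                                          np.sort(b.inside_indices))

    def test_enlarging_workspace_never_shrinks_inside_set(self):
        rng = np.random.default_rng(10)
        spec = random_spec(rng)
        cloud = PointCloud(points=rng.uniform([-800, -600, 200],
                                              [800, 600, 3000], (5000, 3)))
        base = set(filter_cloud(cloud, spec, FilterStrategy.TRAP_ONLY)
                   .inside_indices.tolist())
        import dataclasses
        for grown in (dataclasses.replace(spec, width=spec.width * 1.5),
                      dataclasses.replace(spec, height1=spec.height1 * 1.5,
                                          height2=max(spec.height2,
                                                      spec.height1 * 1.5)),
                      dataclasses.replace(spec, height2=spec.height2 * 1.5)):
            bigger = set(filter_cloud(cloud, grown, FilterStrategy.TRAP_ONLY)
                         .inside_indices.tolist())
            assert base <= bigger

    def test_translation_equivariance(self):
        import dataclasses
        rng = np.random.default_rng(11)
        spec = random_spec(rng)
        pts = rng.uniform([-800, -600, 200], [800, 600, 3000], (5000, 3))
        shift = np.array([123.0, -45.0, 67.0])
        moved = dataclasses.replace(spec, home=spec.home + shift,
                                    fruit=spec.fruit + shift)
        a = filter_cloud(PointCloud(points=pts), spec, FilterStrategy.TRAP_ONLY)
        b = filter_cloud(PointCloud(points=pts + shift), moved,
                         FilterStrategy.TRAP_ONLY)
        np.testing.assert_array_equal(a.inside_indices, b.inside_indices)
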