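import numpy as np
import pytest

from phenokit import imgcore, landmarks

from conftest import make_disk, make_star, single_contour


class TestAngleProfile:
    def test_square_corner_angles_are_90(self, square_mask):
        c = single_contour(square_mask)
        prof = landmarks.angle_profile(c, 10)
        assert prof.min() == pytest.approx(90.0, abs=2.0)
        # sides far from corners are straight
        assert (prof > 170).sum() > len(prof) / 2

    def test_invariant_to_traversal_reversal(self, star_mask):
        mask, _ = star_mask
        c = single_contour(mask)
        rev = imgcore.Contour(points=c.points[::-1].copy())
        a = landmarks.angle_profile(c, 8)
        b = landmarks.angle_profile(rev, 8)
        assert np.allclose(np.sort(a), np.sort(b))

    def test_invariant_to_ring_rotation(self, square_mask):
        c = single_contour(square_mask)
        rolled = imgcore.Contour(points=np.roll(c.points, 17, axis=0))
        a = landmarks.angle_profile(c, 6)
        b = landmarks.angle_profile(rolled, 6)
        assert np.allclose(np.roll(a, 17), b)

    def test_window_too_large_rejected(self, square_mask):
        c = single_contour(square_mask)
        with pytest.raises(ValueError):
            landmarks.angle_profile(c, len(c) // 2)


class TestAcute:
    def test_square_yields_four_corner_landmarks(self, square_mask):
        c = single_contour(square_mask)
        ls = landmarks.acute(None, square_mask, c, window=10, angle_threshold=120)
        assert len(ls) == 4
        corners = {(10, 10), (49, 10), (10, 49), (49, 49)}
        got = {tuple(p) for p in ls.points.astype(int)}
        assert got == corners
        prof = landmarks.angle_profile(c, 10)
        for p in ls.points.astype(int):
            idx = np.where((c.points == p).all(axis=1))[0][0]
            assert prof[idx] == pytest.approx(90.0, abs=2.0)

    def test_large_circle_has_no_acute_landmarks(self):
        m = make_disk(30)
        c = single_contour(m)
        ls = landmarks.acute(None, m, c, window=5, angle_threshold=120)
        assert len(ls) == 0

    def test_star_tips_and_notches_separated_by_pt_vals(self, star_mask):
        mask, _ = star_mask
        c = single_contour(mask)
        ls = landmarks.acute(None, mask, c, window=12, angle_threshold=120)
        assert len(ls) == 10
        tips = ls.pt_vals > 200
        notches = ls.pt_vals < 50
        assert tips.sum() == 5 and notches.sum() == 5

    def test_run_wrapping_across_ring_seam(self, square_mask):
        # roll the contour so a corner run straddles the start index
        c = single_contour(square_mask)
        prof = landmarks.angle_profile(c, 10)
        corner_idx = int(np.argmin(prof))
        rolled = imgcore.Contour(points=np.roll(c.points, -corner_idx, axis=0))
        ls = landmarks.acute(None, square_mask, rolled, 10, 120)
        assert len(ls) == 4


class TestAcuteVertex:
    def test_stride_one_reproduces_acute(self, square_mask):
        c = single_contour(square_mask)
        full = landmarks.acute(None, square_mask, c, 10, 120)
        strided = landmarks.acute_vertex(None, c, 10, 120, search_stride=1)
        assert np.array_equal(full.points, strided.points)

    def test_stride_five_positions_within_stride(self, star_mask):
        mask, _ = star_mask
        c = single_contour(mask)
        full = landmarks.acute(None, mask, c, 12, 120)
        strided = landmarks.acute_vertex(None, c, 12, 120, search_stride=5)
        assert len(strided) == len(full)
        for p in strided.points:
            d = np.abs(full.points - p).sum(axis=1).min()
            assert d <= 5 * 2  # within stride steps along the contour

    def test_stride_longer_than_contour_rejected(self, square_mask):
        c = single_contour(square_mask)
        with pytest.raises(ValueError):
            landmarks.acute_vertex(None, c, 10, 120, search_stride=len(c) + 1)


class TestAxisPseudolandmarks:
    def test_sixty_points_twenty_per_role(self, star_mask):
        mask, _ = star_mask
        for fn, roles in ((landmarks.x_axis_pseudolandmarks,
                           {"x_top", "x_bottom", "x_center"}),
                          (landmarks.y_axis_pseudolandmarks,
                           {"y_left", "y_right", "y_center"})):
            ls = fn(None, mask)
            assert len(ls) == 60
            for r in roles:
                assert sum(1 for x in ls.roles if x == r) == 20

    def test_rectangle_symmetry(self):
        m = np.zeros((40, 80), np.uint8)
        m[10:30, 5:75] = 255
        ls = landmarks.x_axis_pseudolandmarks(None, m)
        pts = ls.points
        roles = np.array(ls.roles)
        assert (pts[roles == "x_top", 1] == 10).all()
        assert (pts[roles == "x_bottom", 1] == 29).all()
        assert np.allclose(pts[roles == "x_center", 1], 19.5)

    def test_right_triangle_matches_slab_scan_oracle(self):
        from skimage.draw import polygon

        m = np.zeros((60, 60), np.uint8)
        rr, cc = polygon([50, 50, 10], [5, 55, 5], shape=m.shape)
        m[rr, cc] = 255
        ls = landmarks.x_axis_pseudolandmarks(None, m)
        ys, xs = np.nonzero(m > 0)
        edges = np.linspace(xs.min(), xs.max() + 1, 21)
        pts, roles = ls.points, np.array(ls.roles)
        for b in range(20):
            sel = (xs >= edges[b]) & (xs < edges[b + 1])
            assert pts[roles == "x_top"][b][1] == ys[sel].min()
            assert pts[roles == "x_bottom"][b][1] == ys[sel].max()
            assert pts[roles == "x_center"][b][0] == pytest.approx(xs[sel].mean())
            assert pts[roles == "x_center"][b][1] == pytest.approx(ys[sel].mean())

    def test_narrow_object_rejected(self):
        m = np.zeros((50, 50), np.uint8)
        m[5:45, 20:30] = 255  # 10 px wide < 20 bins
        with pytest.raises(ValueError):
            landmarks.x_axis_pseudolandmarks(None, m)


class TestScaleAndDistances:
    def test_bbox_corners_map_to_unit_square(self, star_mask):
        mask, _ = star_mask
        ys, xs = np.nonzero(mask > 0)
        corners = landmarks.LandmarkSet(
            points=np.array([[xs.min(), ys.min()], [xs.max(), ys.max()]],
                            float),
            roles=["acute", "acute"])
        scaled, c, b = landmarks.scale_features(corners, mask, (0, 0), (0, 0))
        assert np.allclose(scaled.points, [[0, 0], [1, 1]])

    def test_all_rescaled_landmarks_in_unit_square(self, star_mask):
        mask, _ = star_mask
        ls = landmarks.x_axis_pseudolandmarks(None, mask)
        scaled, _, _ = landmarks.scale_features(ls, mask, (0, 0), (0, 0))
        assert (scaled.points >= 0).all() and (scaled.points <= 1).all()

    def test_collinear_distance_ratios_preserved(self, square_mask):
        pts = landmarks.LandmarkSet(
            points=np.array([[10, 10], [20, 20], [40, 40]], float),
            roles=["acute"] * 3)
        scaled, _, _ = landmarks.scale_features(pts, square_mask, (0, 0), (0, 0))
        p = scaled.points
        assert np.linalg.norm(p[1] - p[0]) / np.linalg.norm(p[2] - p[1]) \
            == pytest.approx(0.5)

    def test_degenerate_bbox_rejected(self):
        m = np.zeros((20, 20), np.uint8)
        m[5:15, 7] = 255  # zero-width bounding box
        pts = landmarks.LandmarkSet(points=np.zeros((1, 2)), roles=["acute"])
        with pytest.raises(ValueError):
            landmarks.scale_features(pts, m, (0, 0), (0, 0))

    def test_reference_distance_345_triangle(self):
        ls = landmarks.LandmarkSet(points=np.array([[0.8, 0.9]]), roles=["acute"])
        df = landmarks.landmark_reference_pt_dist(ls, (0.5, 0.5), (0.5, 0.5))
        row = df[df.ref == "centroid"].iloc[0]
        assert row.dx == pytest.approx(0.3)
        assert row.dy == pytest.approx(0.4)
        assert row.dist == pytest.approx(0.5)

    def test_landmark_on_centroid_gives_zero_features(self):
        ls = landmarks.LandmarkSet(points=np.array([[0.5, 0.5]]), roles=["acute"])
        df = landmarks.landmark_reference_pt_dist(ls, (0.5, 0.5), (0.1, 0.1))
        row = df[df.ref == "centroid"].iloc[0]
        assert row.dx == 0 and row.dy == 0 and row.dist == 0

    def test_empty_landmark_set_gives_empty_table(self, square_mask):
        ls = landmarks.LandmarkSet(points=np.empty((0, 2)), roles=[])
        df = landmarks.landmark_reference_pt_dist(ls, (0, 0), (1, 1))
        assert len(df) == 0

    def test_features_invariant_to_scale_and_translation(self):
        from skimage.draw import polygon

        def features(mask):
            ls = landmarks.x_axis_pseudolandmarks(None, mask)
            ys, xs = np.nonzero(mask > 0)
            centroid = (xs.mean(), ys.mean())
            base = landmarks.plant_base_point(mask)
            scaled, c, b = landmarks.scale_features(ls, mask, centroid, base)
            return landmarks.landmark_reference_pt_dist(scaled, c, b)

        m1 = np.zeros((80, 80), np.uint8)
        rr, cc = polygon([60, 60, 10], [10, 70, 40], shape=m1.shape)
        m1[rr, cc] = 255
        m2 = np.zeros((160, 160), np.uint8)
        rr, cc = polygon([140, 140, 40], [30, 150, 90], shape=m2.shape)
        m2[rr, cc] = 255
        f1 = features(m1)[["dx", "dy", "dist"]].to_numpy()
        f2 = features(m2)[["dx", "dy", "dist"]].to_numpy()
        assert np.abs(f1 - f2).max() < 0.02

    def test_star_tip_distances_match_geometry(self, star_mask):
        mask, tips = star_mask
        c = single_contour(mask)
        ls = landmarks.acute(None, mask, c, window=12, angle_threshold=120)
        tip_pts = ls.points[ls.pt_vals > 200]
        center = (55.0, 55.0)
        df = landmarks.landmark_reference_pt_dist(
            landmarks.LandmarkSet(points=tip_pts, roles=["acute"] * len(tip_pts)),
            center, center)
        d = df[df.ref == "centroid"]["dist"].to_numpy()
        assert np.allclose(d, 50.0, atol=3.0)  # tips drawn on radius 50


class TestExport:
    def test_landmark_table_round_trips(self, tmp_path, star_mask):
        import pandas as pd

        mask, _ = star_mask
        c = single_contour(mask)
        ls = landmarks.acute(None, mask, c, 12, 120)
        path = tmp_path / "lm.tsv"
        landmarks.write_landmark_table(ls, str(path))
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == ["role", "x", "y", "pt_val"]
        assert len(df) == len(ls)
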