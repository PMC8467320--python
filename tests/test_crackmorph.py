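"""Crack morphometry: labeling, contours, hulls, Feret, moment ellipse,
and the six descriptors against analytic shapes and brute-force oracles."""

import numpy as np
import pytest

from ppdxdeg import crackmorph as cm

from conftest import digitize_disk, digitize_ellipse, measure_single


def brute_force_hull_vertices(pts: np.ndarray) -> set:
    """O(n^3) half-plane oracle: (i, j) is a hull edge iff every other
    point lies strictly on its left."""
    n = len(pts)
    vertices = set()
    for i in range(n):
        d = pts - pts[i]
        cross = d[:, 0][:, None] * d[:, 1][None, :] - d[:, 1][:, None] * d[:, 0][None, :]
        # cross[j, k] = (pj-pi) x (pk-pi)
        for j in range(n):
            if j == i:
                continue
            others = np.delete(cross[j], [i, j])
            if np.all(others > 0):
                vertices.add(i)
                vertices.add(j)
    return vertices


class TestLabeling:
    def test_diagonal_pixels_connectivity(self):
        diag = np.array([[1, 0], [0, 1]], np.uint8)
        assert cm.label_components(diag, 8)[1] == 1
        assert cm.label_components(diag, 4)[1] == 2

    def test_labels_in_row_major_first_seen_order(self):
        m = np.zeros((5, 9), np.uint8)
        m[0, 7] = 1   # first in row-major order
        m[2, 1] = 1
        m[4, 4] = 1
        lab, n = cm.label_components(cm.BinaryMask(m, 1.0))
        assert n == 3
        assert lab[0, 7] == 1 and lab[2, 1] == 2 and lab[4, 4] == 3

    def test_hundred_random_rectangles_counted(self, rng):
        m = np.zeros((200, 200), np.uint8)
        for k in range(100):
            r0 = (k // 10) * 20 + 2
            c0 = (k % 10) * 20 + 2
            h = int(rng.integers(2, 14))
            w = int(rng.integers(2, 14))
            m[r0 : r0 + h, c0 : c0 + w] = 1
        assert cm.label_components(cm.BinaryMask(m, 1.0))[1] == 100


class TestTraceBoundary:
    def test_single_pixel_unit_square(self):
        m = np.zeros((3, 3), np.uint8)
        m[1, 1] = 1
        lab, _ = cm.label_components(cm.BinaryMask(m, 1.0))
        poly = cm.trace_boundary(lab, 1)
        assert len(poly) == 4
        assert cm._polygon_area(poly) == pytest.approx(1.0)

    def test_rectangle_four_corners_perimeter_ten(self):
        m = np.zeros((4, 5), np.uint8)
        m[1:3, 1:4] = 1  # 3 wide x 2 tall
        lab, _ = cm.label_components(cm.BinaryMask(m, 1.0))
        poly = cm.trace_boundary(lab, 1)
        assert len(poly) == 4
        closed = np.vstack([poly, poly[:1]])
        perim = np.sum(np.hypot(*np.diff(closed, axis=0).T))
        assert perim == pytest.approx(10.0)

    def test_polygon_is_counterclockwise(self):
        m = np.zeros((6, 6), np.uint8)
        m[1:4, 1:5] = 1
        lab, _ = cm.label_components(cm.BinaryMask(m, 1.0))
        poly = cm.trace_boundary(lab, 1)
        x, y = poly[:, 0], poly[:, 1]
        signed = (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2
        assert signed > 0

    def test_disk_polygon_area_within_1pct(self):
        disk = digitize_disk(40)
        lab, _ = cm.label_components(cm.BinaryMask(disk, 1.0))
        poly = cm.trace_boundary(lab, 1)
        assert cm._polygon_area(poly) == pytest.approx(np.pi * 40**2, rel=0.01)

    def test_missing_label_raises(self):
        lab, _ = cm.label_components(cm.BinaryMask(np.ones((2, 2), np.uint8), 1.0))
        with pytest.raises(ValueError, match="label 7"):
            cm.trace_boundary(lab, 7)


class TestConvexHull:
    def test_square_plus_center(self):
        pts = [(0, 0), (2, 0), (2, 2), (0, 2), (1, 1)]
        hull = cm.convex_hull(pts)
        assert len(hull) == 4
        assert (1, 1) not in {tuple(p) for p in hull}

    def test_collinear_input_gives_segment(self):
        hull = cm.convex_hull([(0, 0), (1, 1), (2, 2), (3, 3)])
        assert hull.shape == (2, 2)
        assert {tuple(p) for p in hull} == {(0.0, 0.0), (3.0, 3.0)}

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            cm.convex_hull(np.empty((0, 2)))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            pts = rng.normal(size=(120, 2))
            hull = cm.convex_hull(pts)
            mine = {tuple(p) for p in hull}
            oracle = {tuple(pts[i]) for i in brute_force_hull_vertices(pts)}
            assert mine == oracle


class TestFeret:
    def test_horizontal_segment(self):
        assert cm.feret(np.array([[0.0, 0.0], [10.0, 0.0]])) == (10.0, 0.0, False)

    def test_vertical_segment_is_90_degrees(self):
        d, a, _ = cm.feret(np.array([[0.0, 0.0], [0.0, 7.0]]))
        assert (d, a) == (7.0, 90.0)

    def test_single_vertex_degenerate(self):
        res = cm.feret(np.array([[1.0, 2.0]]))
        assert res.diameter == 0.0 and res.angle_deg == 0.0 and res.degenerate

    def test_calipers_equals_exhaustive_on_random_hulls(self, rng):
        for _ in range(200):
            pts = rng.normal(size=(rng.integers(4, 40), 2)) * rng.uniform(0.5, 20)
            hull = cm.convex_hull(pts)
            d, _, _ = cm.feret(hull)
            d2 = np.sqrt(
                (((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)).max()
            )
            assert d == pytest.approx(d2, rel=1e-12)


class TestFitEllipse:
    def test_digitized_3_to_1_ellipse(self):
        ell = digitize_ellipse(60, 20)
        lab, _ = cm.label_components(cm.BinaryMask(ell, 1.0))
        major, minor, theta = cm.fit_ellipse(lab, 1)
        assert major / minor == pytest.approx(3.0, abs=0.05)
        assert min(theta, 180 - theta) < 2.0

    def test_disk_aspect_ratio_unity(self):
        lab, _ = cm.label_components(cm.BinaryMask(digitize_disk(30), 1.0))
        major, minor, _ = cm.fit_ellipse(lab, 1)
        assert major / minor == pytest.approx(1.0, abs=0.02)

    def test_square_degenerates_to_unit_aspect(self):
        m = np.zeros((20, 20), np.uint8)
        m[5:15, 5:15] = 1
        lab, _ = cm.label_components(cm.BinaryMask(m, 1.0))
        major, minor, _ = cm.fit_ellipse(lab, 1)
        assert major / minor == pytest.approx(1.0, abs=0.01)

    def test_orientation_follows_rotation(self):
        ell = digitize_ellipse(50, 12, angle_deg=30.0)
        lab, _ = cm.label_components(cm.BinaryMask(ell, 1.0))
        _, _, theta = cm.fit_ellipse(lab, 1)
        assert theta == pytest.approx(30.0, abs=2.0)


class TestMeasureCrack:
    def test_disk_descriptors(self):
        rec = measure_single(digitize_disk(40), 0.1)
        assert rec.circularity >= 0.95
        assert rec.solidity >= 0.98
        assert rec.aspect_ratio == pytest.approx(1.0, abs=0.02)
        assert rec.area == pytest.approx(np.pi * 16.0, rel=0.01)

    def test_rectangle_solidity_unity(self):
        m = np.zeros((30, 50), np.uint8)
        m[5:25, 5:45] = 1
        rec = measure_single(m)
        assert rec.solidity == pytest.approx(1.0, abs=0.02)

    def test_thin_rectangle_circularity_low(self):
        m = np.zeros((20, 120), np.uint8)
        m[5:15, 5:105] = 1  # 10:1
        rec = measure_single(m)
        assert rec.circularity < 0.4

    def test_scale_equivariance(self):
        ell = digitize_ellipse(40, 12, angle_deg=25)
        r1 = measure_single(ell, 1.0)
        r2 = measure_single(ell, 2.0)
        assert r2.feret_diameter == pytest.approx(2 * r1.feret_diameter)
        assert r2.perimeter == pytest.approx(2 * r1.perimeter)
        assert r2.area == pytest.approx(4 * r1.area)
        for f in ("aspect_ratio", "circularity", "solidity", "feret_angle"):
            assert getattr(r2, f) == pytest.approx(getattr(r1, f))

    @pytest.mark.parametrize("angle", [0, 22.5, 45, 77, 101, 150])
    def test_rotation_robustness_within_3pct(self, angle):
        base = measure_single(digitize_ellipse(50, 16, 0.0))
        rot = measure_single(digitize_ellipse(50, 16, angle))
        assert rot.feret_diameter == pytest.approx(base.feret_diameter, rel=0.03)
        assert rot.area == pytest.approx(base.area, rel=0.03)
        assert rot.aspect_ratio == pytest.approx(base.aspect_ratio, rel=0.03)
        assert abs(rot.feret_angle - angle % 180) < 3.0

    def test_descriptor_bounds_on_random_blobs(self, rng):
        m = np.zeros((120, 120), np.uint8)
        for _ in range(12):
            r, c = rng.integers(15, 105, 2)
            rad = int(rng.integers(2, 9))
            m[
                max(0, r - rad) : r + rad, max(0, c - rad) : c + rad
            ] |= digitize_disk(rad, pad=0)[: 2 * rad, : 2 * rad]
        for rec in cm.measure_all(cm.BinaryMask(m, 0.5)):
            assert 0.0 <= rec.circularity <= 1.0
            assert 0.0 < rec.solidity <= 1.0
            assert rec.aspect_ratio >= 1.0
            assert 0.0 <= rec.feret_angle < 180.0

    def test_border_component_flagged(self):
        m = np.zeros((10, 10), np.uint8)
        m[0:3, 4:7] = 1
        rec = cm.measure_all(cm.BinaryMask(m, 1.0))[0]
        assert rec.touches_border

    def test_agrees_with_regionprops_oracle(self, rng):
        pytest.importorskip("skimage")
        from skimage.measure import regionprops

        ell = digitize_ellipse(45, 15, angle_deg=60)
        lab, _ = cm.label_components(cm.BinaryMask(ell, 1.0))
        rp = regionprops(lab)[0]
        rec = cm.measure_all(cm.BinaryMask(ell, 1.0))[0]
        assert rec.area == pytest.approx(rp.area)
        assert rec.feret_diameter == pytest.approx(rp.feret_diameter_max, rel=0.02)
        # hull-fill conventions differ slightly between the two libraries
        assert rec.solidity == pytest.approx(rp.solidity, abs=0.03)
        assert rec.aspect_ratio == pytest.approx(
            rp.axis_major_length / rp.axis_minor_length, rel=0.03
        )


class TestSummaries:
    def rec(self, **kw):
        base = dict(
            label=1, area=1.0, perimeter=1.0, feret_diameter=1.0,
            feret_angle=90.0, aspect_ratio=1.0, circularity=1.0, solidity=1.0,
        )
        base.update(kw)
        return cm.CrackRecord(**base)

    def test_single_record(self):
        s = cm.summarize_cracks([self.rec(area=4.0)], descriptors=("area",))["area"]
        assert s.mean == s.median == 4.0 and s.sd == 0.0

    def test_hand_arithmetic(self):
        recs = [self.rec(area=v) for v in (1.0, 2.0, 3.0)]
        s = cm.summarize_cracks(recs, descriptors=("area",))["area"]
        assert (s.mean, s.median, s.sd) == (2.0, 2.0, 1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cm.summarize_cracks([])

    def test_angle_population_centers_near_90(self, rng):
        # cracks perpendicular to the fiber axis: angles ~ N(90, 20)
        angles = rng.normal(90, 20, 200) % 180
        recs = [self.rec(feret_angle=a) for a in angles]
        s = cm.summarize_cracks(recs, descriptors=("feret_angle",))["feret_angle"]
        assert abs(s.mean - 90) < 5


class TestMaskIO:
    def test_pgm_round_trip_with_sidecar(self, tmp_path):
        m = cm.BinaryMask(digitize_disk(6), 0.066)
        path = tmp_path / "m.pgm"
        cm.write_mask(m, path)
        back = cm.read_mask(path)
        assert back.pixel_size == 0.066
        assert np.array_equal(back.pixels, m.pixels)

    def test_png_round_trip(self, tmp_path):
        pytest.importorskip("imageio")
        m = cm.BinaryMask(digitize_disk(5), 0.1)
        path = tmp_path / "m.png"
        cm.write_mask(m, path)
        back = cm.read_mask(path, pixel_size=0.1)
        assert np.array_equal(back.pixels, m.pixels)

    def test_missing_sidecar_rejected(self, tmp_path):
        m = cm.BinaryMask(digitize_disk(5), 0.1)
        path = tmp_path / "m.pgm"
        cm.write_mask(m, path)
        (tmp_path / "m.pgm.json").unlink()
        with pytest.raises(ValueError, match="sidecar"):
            cm.read_mask(path)
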