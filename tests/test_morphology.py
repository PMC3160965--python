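"""Benkrid perimeter, circularity, shape classes, radial profiles."""

import math
import warnings

import numpy as np
import pytest

from palm_mcquant import morphology as mo
from palm_mcquant import synth


def _disk_mask(r, off=(0.0, 0.0)):
    n = int(2 * r + 20)
    lab, _ = synth.simulate_shapes(
        synth.ShapeSimConfig(
            canvas_px=(n, n),
            shapes=(synth.ShapeSpec("disk", (n / 2 + off[0], n / 2 + off[1]),
                                    radius=r),),
        )
    )
    return lab == 1


class TestBenkridPerimeter:
    def test_rectangle_center_to_center_contour(self):
        """Filled w×h rectangle: closed contour through edge-pixel centers has
        length 2·((w−1) + (h−1))."""
        m = np.zeros((20, 24), bool)
        m[5:11, 4:14] = True  # h=6, w=10
        assert mo.benkrid_perimeter(m) == pytest.approx(2 * (9 + 5))

    def test_diagonal_staircase_doubled_path(self):
        k = 6
        m = np.zeros((12, 12), bool)
        for i in range(k):
            m[2 + i, 2 + i] = True
        assert mo.benkrid_perimeter(m) == pytest.approx(2 * (k - 1) * math.sqrt(2))

    def test_single_pixel_convention(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        assert mo.benkrid_perimeter(m) == 4.0

    def test_domino_convention(self):
        m = np.zeros((5, 5), bool)
        m[2, 2:4] = True
        assert mo.benkrid_perimeter(m) == 6.0

    def test_disconnected_mask_rejected(self):
        m = np.zeros((8, 8), bool)
        m[1, 1] = True
        m[6, 6] = True
        with pytest.raises(ValueError):
            mo.benkrid_perimeter(m)

    def test_l_shape_hand_trace(self):
        # L of 3x3 with one 2x1 arm removed: trace by hand
        m = np.zeros((8, 8), bool)
        m[2:5, 2:5] = True
        m[2, 4] = False
        m[3, 4] = False
        # manual Moore trace: (2,2)→(2,3)→(3,3)→(4,4)→(4,3)→(4,2)→(3,2)→(2,2)
        # six straight links plus one diagonal
        per = mo.benkrid_perimeter(m)
        assert per == pytest.approx(6 + math.sqrt(2))


class TestCircularity:
    def test_analytic_circle_is_one(self):
        r = 100.0
        assert mo.circularity(math.pi * r**2, 2 * math.pi * r) == pytest.approx(1.0)

    def test_square_closed_form(self):
        s = 7.0
        assert mo.circularity(s * s, 4 * s) == pytest.approx(math.pi / 4)

    def test_rasterized_disk_near_one(self):
        m = _disk_mask(30.0)
        c = mo.circularity(m.sum(), mo.benkrid_perimeter(m))
        assert 0.9 <= c <= 1.1

    def test_rasterized_disks_close_to_one_at_both_scales(self):
        for r in (10.0, 50.0):
            m = _disk_mask(r)
            c = mo.circularity(m.sum(), mo.benkrid_perimeter(m))
            assert abs(c - 1.0) < 0.15

    def test_isoperimetric_bound_on_polygon_fixtures(self):
        # analytic (a, p) pairs: C ≤ 1 always
        for spec in (
            synth.ShapeSpec("rectangle", (0, 0), size=(10, 3)),
            synth.ShapeSpec("star", (0, 0), n_points=5, r_outer=20, r_inner=7),
            synth.ShapeSpec("ellipse", (0, 0), semi_axes=(15, 5)),
        ):
            a, p = synth._analytic_area_perimeter(spec)
            assert mo.circularity(a, p) <= 1.0 + 1e-12

    def test_rotation_robustness_of_rasterized_ellipse(self):
        cs = []
        for rot in (0.0, 45.0):
            lab, _ = synth.simulate_shapes(
                synth.ShapeSimConfig(
                    canvas_px=(80, 80),
                    shapes=(synth.ShapeSpec("ellipse", (40.0, 40.0),
                                            semi_axes=(20, 10),
                                            rotation_deg=rot),),
                )
            )
            m = lab == 1
            cs.append(mo.circularity(m.sum(), mo.benkrid_perimeter(m)))
        assert abs(cs[0] - cs[1]) < 0.05

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mo.circularity(0.0, 10.0)
        with pytest.raises(ValueError):
            mo.circularity(10.0, -1.0)


class TestClassifyCircularity:
    @pytest.mark.parametrize(
        "c,expected",
        [
            (0.9, "highly_circular"),
            (0.66, "highly_circular"),  # inclusive bound
            (0.5, "intermediate"),
            (0.33, "intermediate"),  # inclusive bound
            (0.1, "irregular"),
        ],
    )
    def test_classes(self, c, expected):
        assert mo.classify_circularity(c) == expected


class TestNormalizedRadius:
    geom = mo.CellGeometry(center_nm=(1000.0, 1000.0), radius_nm=500.0)

    def test_center_zero_edge_one_half_half(self):
        assert mo.normalized_radius((1000.0, 1000.0), self.geom) == 0.0
        assert mo.normalized_radius((1500.0, 1000.0), self.geom) == pytest.approx(1.0)
        assert mo.normalized_radius((1000.0, 1250.0), self.geom) == pytest.approx(0.5)

    def test_beyond_edge_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            assert mo.normalized_radius((2000.0, 1000.0), self.geom) == 1.0

    @pytest.mark.parametrize("r,expected", [(0.85, True), (0.5, False),
                                            (0.7, True), (1.0, True)])
    def test_periphery_band(self, r, expected):
        assert mo.periphery_filter(r) is expected


def _shape(c, r):
    return mo.ClusterShape(0, 10.0, 10.0, c, mo.classify_circularity(c),
                           (0.0, 0.0), r)


class TestRadialProfiles:
    def test_constant_circularity_every_occupied_bin(self):
        shapes = [_shape(0.7, r) for r in (0.1, 0.3, 0.6, 0.9)]
        prof = mo.radial_circularity_profile(shapes)
        assert np.allclose(prof.mean, 0.7)
        assert list(prof.bin_centers) == [0.125, 0.375, 0.625, 0.875]

    def test_empty_bins_reported_missing(self):
        shapes = [_shape(0.5, 0.875) for _ in range(3)]
        prof = mo.radial_circularity_profile(shapes)
        assert np.isnan(prof.mean[:3]).all()
        assert prof.mean[3] == pytest.approx(0.5)
        assert prof.counts.tolist() == [0, 0, 0, 3]

    def test_commanded_radial_gradient_recovered(self):
        rng = np.random.default_rng(0)
        shapes = []
        commanded = {0.125: 0.3, 0.375: 0.5, 0.625: 0.7, 0.875: 0.9}
        for center, cval in commanded.items():
            for _ in range(50):
                shapes.append(_shape(
                    float(np.clip(cval + rng.normal(0, 0.03), 0, 1)),
                    center + rng.uniform(-0.1, 0.1),
                ))
            rng.shuffle(shapes)
        prof = mo.radial_circularity_profile(shapes)
        for i, cval in enumerate(commanded.values()):
            assert prof.mean[i] == pytest.approx(cval, abs=0.02)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        shapes = [_shape(rng.random(), rng.random()) for _ in range(40)]
        p1 = mo.radial_circularity_profile(shapes)
        rng.shuffle(shapes)
        p2 = mo.radial_circularity_profile(shapes)
        assert np.allclose(p1.mean, p2.mean, equal_nan=True)

    def test_uniform_image_flat_profile(self):
        geom = mo.CellGeometry(center_nm=(500.0, 500.0), radius_nm=400.0)
        prof = mo.radial_intensity_profile(np.full((50, 50), 3.0), geom, 20.0,
                                           bin_width=0.25)
        assert np.allclose(prof.mean[~np.isnan(prof.mean)], 1.0)

    def test_ring_peak_recovered_in_band(self):
        """Synthetic actin-like ring at r̃ = 0.8 peaks in the 0.75–0.85 bin."""
        geom = mo.CellGeometry(center_nm=(500.0, 500.0), radius_nm=450.0)
        yy, xx = np.mgrid[0:50, 0:50]
        r = np.hypot((xx + 0.5) * 20 - 500, (yy + 0.5) * 20 - 500) / 450.0
        img = np.exp(-((r - 0.8) ** 2) / (2 * 0.05**2))
        prof = mo.radial_intensity_profile(img, geom, 20.0, bin_width=0.05)
        peak_bin = np.nanargmax(prof.mean)
        assert 0.75 <= prof.bin_centers[peak_bin] <= 0.85
        assert np.nanmax(prof.mean) == 1.0

    def test_all_zero_image_is_error(self):
        geom = mo.CellGeometry(center_nm=(100.0, 100.0), radius_nm=90.0)
        with pytest.raises(ValueError, match="no signal"):
            mo.radial_intensity_profile(np.zeros((10, 10)), geom, 20.0)


class TestCellGeometry:
    def test_min_enclosing_circle_of_disk_footprint(self):
        lab, _ = synth.simulate_shapes(
            synth.ShapeSimConfig(
                canvas_px=(100, 100),
                shapes=(synth.ShapeSpec("disk", (50.0, 50.0), radius=30.0),),
            )
        )
        geom = mo.cell_geometry_from_footprint((lab > 0).astype(float), 100.0)
        assert geom.center_nm[0] == pytest.approx(50.0 * 100, rel=0.02)
        assert geom.center_nm[1] == pytest.approx(50.0 * 100, rel=0.02)
        assert geom.radius_nm == pytest.approx(30.0 * 100, rel=0.05)

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError):
            mo.CellGeometry(center_nm=(0, 0), radius_nm=0.0)


class TestMeasureShapes:
    def test_disk_and_star_classes(self):
        lab, truth = synth.simulate_shapes(
            synth.ShapeSimConfig(
                canvas_px=(160, 160),
                shapes=(
                    synth.ShapeSpec("disk", (40.0, 40.0), radius=20.0),
                    synth.ShapeSpec("star", (110.0, 110.0), n_points=7,
                                    r_outer=30.0, r_inner=15.0),
                ),
            )
        )
        geom = mo.CellGeometry(center_nm=(80.0, 80.0), radius_nm=120.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # star centroid may clip r̃
            shapes = mo.measure_shapes(lab, 1.0, geometry=geom)
        by_label = {s.label: s for s in shapes}
        assert by_label[1].shape_class == "highly_circular"
        assert by_label[2].shape_class == "irregular"  # spiky star
        # centroid distances from the (80, 80) cell center over radius 120
        assert by_label[1].r_norm == pytest.approx(math.hypot(40, 40) / 120, abs=0.01)
        assert by_label[2].r_norm == pytest.approx(math.hypot(30.5, 30.5) / 120, abs=0.01)
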