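"""Vessel-diameter pipeline: thresholding, centerline, chords, recovery."""

import numpy as np
import pytest
from scipy import ndimage

from lymphomorph import synthetic_data as sd
from lymphomorph import vessel_morphometry as vm
from lymphomorph.imaging_io import BinaryMask, VesselImage


def brute_force_otsu(values: np.ndarray) -> float:
    """Independent oracle: per-cut scan of inter-class variance on raw pixels.

    Same candidate cut points (the interior edges of a 256-bin histogram of
    the intensity range) but class weights and means computed directly from
    the raw pixel partition, one cut at a time.
    """
    values = values.ravel().astype(np.float64)
    vmin, vmax = values.min(), values.max()
    edges = np.histogram_bin_edges(values, bins=256, range=(vmin, vmax))
    cuts = edges[1:-1]
    scores = []
    for t in cuts:
        fg = values > t
        n1 = fg.sum()
        if n1 == 0 or n1 == values.size:
            scores.append(-np.inf)
            continue
        w1 = n1 / values.size
        w0 = 1.0 - w1
        scores.append(w0 * w1 * (values[fg].mean() - values[~fg].mean()) ** 2)
    scores = np.asarray(scores)
    best = scores.max()
    plateau = np.flatnonzero(scores >= best * (1 - 1e-12))
    return float(0.5 * (cuts[plateau[0]] + cuts[plateau[-1]]))


class TestOtsu:
    def test_two_valued_image_thresholds_at_plateau_midpoint(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[:, 5:] = 255
        thr = vm.compute_otsu_threshold(img)
        assert abs(thr - 127.5) < 1.0
        # both classes recovered exactly under the strictly-greater rule
        assert ((img > thr) == (img == 255)).all()

    def test_constant_image_has_no_threshold(self):
        with pytest.raises(vm.VesselError, match="no threshold"):
            vm.compute_otsu_threshold(np.full((8, 8), 42.0))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle_on_random_images(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(48, 48)).astype(np.uint8)
        assert vm.compute_otsu_threshold(img) == pytest.approx(
            brute_force_otsu(img), abs=1e-9
        )

    def test_matches_oracle_on_bimodal_image(self, rng):
        img = np.concatenate(
            [rng.normal(50, 10, 2000), rng.normal(180, 15, 1500)]
        ).reshape(50, 70)
        assert vm.compute_otsu_threshold(img) == pytest.approx(
            brute_force_otsu(img), abs=1e-9
        )


class TestCleanMask:
    def test_small_speckle_removed(self):
        grid = np.zeros((20, 20), dtype=bool)
        grid[3, 3:6] = True  # 3-px speckle
        out = vm.clean_mask(BinaryMask(grid), min_object_px=10, closing_radius_px=0)
        assert not out.grid.any()

    def test_solid_rectangle_unchanged_and_idempotent(self):
        grid = np.zeros((20, 60), dtype=bool)
        grid[6:13, 5:55] = True  # 50x7 rectangle
        out = vm.clean_mask(BinaryMask(grid), min_object_px=10, closing_radius_px=1)
        np.testing.assert_array_equal(out.grid, grid)
        out2 = vm.clean_mask(out, min_object_px=10, closing_radius_px=1)
        np.testing.assert_array_equal(out2.grid, out.grid)

    def test_interior_hole_filled_matches_direct_morphology(self):
        grid = np.zeros((20, 60), dtype=bool)
        grid[6:13, 5:55] = True
        grid[9, 30] = False
        expected = ndimage.binary_fill_holes(grid)
        out = vm.clean_mask(BinaryMask(grid), min_object_px=10, closing_radius_px=1)
        np.testing.assert_array_equal(out.grid, expected)


class TestCenterline:
    def test_straight_rectangle_yields_one_midrow_branch(self):
        grid = np.zeros((21, 110), dtype=bool)
        grid[6:15, 5:105] = True  # 100x9, midrow 10
        cl = vm.extract_centerline(BinaryMask(grid), prune_px=5)
        assert cl.n_branches == 1
        pts = cl.branches[0].points
        # skeleton retracts ~width/2 from each end
        assert cl.branches[0].length_px == pytest.approx(92, abs=3)
        assert np.allclose(pts[:, 0], 10, atol=1)

    def test_y_shape_decomposes_into_three_branches_at_one_junction(self):
        grid = np.zeros((100, 140), dtype=bool)
        grid[47:54, 5:70] = True  # stem
        yy, xx = np.mgrid[0:100, 0:140]
        for sign in (+1, -1):
            # two arms at +/-45 degrees from (67, 50)
            d = np.abs((yy - 50) - sign * (xx - 67)) / np.sqrt(2)
            along = ((xx - 67) + sign * (yy - 50)) / np.sqrt(2)
            grid |= (d <= 3.5) & (along >= 0) & (along <= 60)
        cl = vm.extract_centerline(BinaryMask(grid), prune_px=5)
        assert cl.n_branches == 3
        assert len(cl.junctions) >= 1

    def test_empty_mask_errors(self):
        with pytest.raises(vm.VesselError, match="empty"):
            vm.extract_centerline(BinaryMask(np.zeros((5, 5), dtype=bool)))

    def test_tiny_blob_errors(self):
        grid = np.zeros((9, 9), dtype=bool)
        grid[4, 4] = True
        with pytest.raises(vm.VesselError, match="too small"):
            vm.extract_centerline(BinaryMask(grid))


class TestTangents:
    def _branch_from(self, points):
        return vm.Centerline([vm.Branch(np.asarray(points, float))], np.empty((0, 2)))

    def test_horizontal_branch(self):
        cl = self._branch_from([(5.0, x) for x in range(30)])
        vm.estimate_tangents(cl)
        t = cl.branches[0].tangents
        np.testing.assert_allclose(np.abs(t[:, 1]), 1.0, atol=1e-6)
        np.testing.assert_allclose(t[:, 0], 0.0, atol=1e-6)

    def test_diagonal_branch_at_45_degrees(self):
        cl = self._branch_from([(i, i) for i in range(30)])
        vm.estimate_tangents(cl)
        ang = np.degrees(np.arctan2(*cl.branches[0].tangents.T))
        np.testing.assert_allclose(ang, 45.0, atol=1.0)

    def test_quarter_circle_tangent_perpendicular_to_radius(self):
        theta = np.linspace(0, np.pi / 2, 80)
        pts = np.stack([50 * np.sin(theta), 50 * np.cos(theta)], axis=1)
        cl = self._branch_from(pts)
        vm.estimate_tangents(cl, window_px=5)
        for i in range(5, 75):  # interior: full windows
            radial = pts[i] / np.linalg.norm(pts[i])
            cos = abs(np.dot(cl.branches[0].tangents[i], radial))
            assert np.degrees(np.arcsin(min(cos, 1.0))) <= 2.0


class TestDiameterMeasurement:
    def test_axis_aligned_rectangle_chord(self):
        grid = np.zeros((30, 60), dtype=bool)
        grid[10:17, 5:55] = True  # height 7
        d, e0, e1 = vm.measure_diameter_at(
            BinaryMask(grid), np.array([13.0, 30.0]), np.array([1.0, 0.0])
        )
        assert d == pytest.approx(7.0, abs=0.2)
        assert np.linalg.norm(e0 - e1) == pytest.approx(d, abs=1e-6)

    def test_rotated_rectangle_chord(self):
        img, _ = sd.gen_vessel_image(
            length_px=80, diameter_px=7.0, orientation_deg=30.0, contrast=100.0
        )
        mask = vm.binarize(img)
        center = (np.asarray(img.shape) - 1) / 2.0
        theta = np.deg2rad(30.0)
        normal = np.array([np.cos(theta), -np.sin(theta)])  # (y, x) perpendicular
        d, _, _ = vm.measure_diameter_at(BinaryMask(mask.grid), center, normal)
        assert d == pytest.approx(7.0, abs=0.5)

    def test_point_outside_mask_errors(self):
        grid = np.zeros((10, 10), dtype=bool)
        grid[4:6, 4:6] = True
        with pytest.raises(vm.VesselError, match="off-vessel"):
            vm.measure_diameter_at(
                BinaryMask(grid), np.array([0.0, 0.0]), np.array([1.0, 0.0])
            )

    def test_dilation_never_decreases_diameters(self):
        img, _ = sd.gen_vessel_image(length_px=60, diameter_px=7.0, seed=4)
        mask = vm.binarize(img)
        bigger = BinaryMask(ndimage.binary_dilation(mask.grid, np.ones((3, 3))))
        center = (np.asarray(img.shape) - 1) / 2.0
        for ang in np.linspace(0, np.pi, 7):
            n = np.array([np.sin(ang), np.cos(ang)])
            d0, _, _ = vm.measure_diameter_at(mask, center, n, max_len_px=200)
            d1, _, _ = vm.measure_diameter_at(bigger, center, n, max_len_px=200)
            assert d1 >= d0 - 1e-9


class TestDiameterProfile:
    def test_straight_tube_profile_in_micrometres(self):
        img, _ = sd.gen_vessel_image(length_px=120, diameter_px=7.0, spacing_um=2.0)
        mask = vm.binarize(img)
        cl = vm.estimate_tangents(vm.extract_centerline(mask))
        prof = vm.diameter_profile(mask, cl, spacing_um=2.0)
        assert np.all(np.abs(prof.diameters_um - 14.0) <= 0.4)

    def test_tapering_tube_profile_is_linear(self):
        # noise+PSF dither the rasterization staircase; the locally averaged
        # profile (10-px arclength bins) must be linear to within half a pixel
        img, _ = sd.gen_vessel_image(
            length_px=200,
            diameter_px=lambda s: 4.0 + 6.0 * s / 200.0,
            orientation_deg=10.0,
            contrast=100.0,
            noise_sigma=10.0,
            psf_sigma_px=0.5,
            seed=5,
        )
        mask = vm.clean_mask(vm.binarize(img), min_object_px=32)
        cl = vm.estimate_tangents(vm.extract_centerline(mask))
        prof = vm.diameter_profile(mask, cl, spacing_um=1.0, junction_exclusion_px=8)
        arcs = np.asarray([s.arclength_um for s in prof.samples])
        edges = np.arange(arcs.min(), arcs.max() + 10, 10)
        idx = np.digitize(arcs, edges)
        binned = np.array(
            [
                (arcs[idx == i].mean(), prof.diameters_um[idx == i].mean())
                for i in np.unique(idx)
                if (idx == i).sum() >= 3
            ]
        )
        fit = np.polyfit(binned[:, 0], binned[:, 1], 1)
        resid = binned[:, 1] - np.polyval(fit, binned[:, 0])
        assert np.abs(resid).max() <= 0.5
        assert fit[0] == pytest.approx(6.0 / 200.0, rel=0.15)

    def test_tube_shorter_than_exclusion_margins_errors(self):
        grid = np.zeros((15, 15), dtype=bool)
        grid[5:10, 4:11] = True
        cl = vm.extract_centerline(BinaryMask(grid), prune_px=0)
        with pytest.raises(vm.VesselError, match="no measurable vessel"):
            vm.diameter_profile(
                BinaryMask(grid), cl, spacing_um=1.0, junction_exclusion_px=10
            )

    def test_scale_covariance_doubling_spacing_doubles_diameters(self):
        img, _ = sd.gen_vessel_image(length_px=80, diameter_px=7.0)
        mask = vm.binarize(img)
        cl = vm.estimate_tangents(vm.extract_centerline(mask))
        d1 = vm.diameter_profile(mask, cl, spacing_um=1.0).diameters_um
        d2 = vm.diameter_profile(mask, cl, spacing_um=2.0).diameters_um
        np.testing.assert_allclose(d2, 2.0 * d1, rtol=1e-12)


class TestSummary:
    def _profile(self, values):
        samples = [
            vm.DiameterSample(0, float(i), float(v), (0, 0), (0, 0))
            for i, v in enumerate(values)
        ]
        return vm.DiameterProfile(samples, spacing_um=1.0)

    def test_constant_samples(self):
        s = vm.summarize_diameters(self._profile([10, 10, 10]))
        assert (s.mean_um, s.sd_um, s.n) == (10.0, 0.0, 3)
        assert s.counts.sum() == s.n

    def test_mean_and_median(self):
        s = vm.summarize_diameters(self._profile([8, 12]))
        assert s.mean_um == 10.0
        assert s.median_um == 10.0

    def test_empty_profile_errors(self):
        with pytest.raises(vm.VesselError, match="empty"):
            vm.summarize_diameters(vm.DiameterProfile([], spacing_um=1.0))


class TestEndToEndRecovery:
    @pytest.mark.parametrize("true_px", [5.0, 10.0, 20.0])
    def test_noisy_tube_mean_diameter_within_5_percent(self, true_px):
        img, truth = sd.gen_vessel_image(
            length_px=150,
            diameter_px=true_px,
            orientation_deg=15.0,
            contrast=100.0,
            noise_sigma=10.0,
            psf_sigma_px=0.5,
            seed=11,
        )
        _, _, _, summary = vm.analyze_vessel_image(img, min_object_px=32)
        assert summary.mean_um == pytest.approx(
            truth.params["mean_diameter_um"], rel=0.05
        )

    def test_rotation_spread_of_mean_diameter_below_half_pixel(self):
        means = []
        for ang in (0.0, 15.0, 30.0, 45.0):
            img, _ = sd.gen_vessel_image(
                length_px=120, diameter_px=7.0, orientation_deg=ang, seed=3
            )
            _, _, _, summary = vm.analyze_vessel_image(img, min_object_px=32)
            means.append(summary.mean_um)
        assert max(means) - min(means) <= 0.5
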