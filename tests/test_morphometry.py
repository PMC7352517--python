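"""Cell-shape metrics, spot detection and CTCF."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from stromascan import (
    FiberImage,
    SpotFieldParams,
    cell_fiber_alignment_angle,
    ctcf,
    ctcf_ratio,
    detect_focal_adhesions,
    generate_cell_mask,
    generate_spot_image,
    shape_metrics,
)


class TestShapeMetrics:
    def test_scale_invariance_of_circularity(self):
        small = generate_cell_mask(2.0, 1000.0, 20.0, 0.25, seed=0)
        big = generate_cell_mask(2.0, 4000.0, 20.0, 0.25, seed=0)
        c_small = shape_metrics(small, 0.25).circularity
        c_big = shape_metrics(big, 0.25).circularity
        assert c_small == pytest.approx(c_big, rel=0.01)

    def test_rotation_invariance_of_circularity(self):
        a = generate_cell_mask(3.0, 3000.0, 0.0, 0.25, seed=0)
        b = generate_cell_mask(3.0, 3000.0, 63.0, 0.25, seed=0)
        assert shape_metrics(a, 0.25).circularity == pytest.approx(
            shape_metrics(b, 0.25).circularity, rel=0.02
        )

    def test_area_matches_requested_area(self):
        mask = generate_cell_mask(1.5, 2000.0, 0.0, 0.25, seed=1)
        assert shape_metrics(mask, 0.25).area_um2 == pytest.approx(
            2000.0, rel=0.01
        )

    def test_multiple_components_rejected(self):
        mask = np.zeros((100, 100), bool)
        mask[10:40, 10:40] = True
        mask[60:90, 60:90] = True
        with pytest.raises(ValueError, match="found 2"):
            shape_metrics(mask, 1.0)

    def test_aspect_ratio_recovered(self):
        mask = generate_cell_mask(4.0, 5000.0, 10.0, 0.25, seed=0)
        assert shape_metrics(mask, 0.25).aspect_ratio == pytest.approx(
            4.0, rel=0.02
        )


class TestAlignmentAngle:
    @pytest.mark.parametrize(
        "cell,fiber,expected",
        [(30.0, 30.0, 0.0), (170.0, 10.0, 20.0), (0.0, 90.0, 90.0),
         (100.0, 40.0, 60.0)],
    )
    def test_axial_difference_folded_to_quadrant(self, cell, fiber, expected):
        assert cell_fiber_alignment_angle(cell, fiber) == pytest.approx(expected)

    def test_mask_input_uses_major_axis(self):
        mask = generate_cell_mask(3.0, 3000.0, 50.0, 0.25, seed=2)
        angle = cell_fiber_alignment_angle(mask, 50.0, pixel_size_um=0.25)
        assert angle < 2.0

    def test_mean_alignment_improves_with_orientation_concentration(self):
        """Cells sampled with tighter angular spread around the fiber axis
        (the readout of stronger contact guidance) score lower angles."""
        rng = np.random.default_rng(8)
        fiber_axis = 45.0
        means = []
        for kappa in (0.5, 2.0, 8.0):
            angles = (
                np.rad2deg(rng.vonmises(np.deg2rad(2 * fiber_axis), kappa, 40))
                / 2 % 180
            )
            vals = [
                cell_fiber_alignment_angle(a, fiber_axis) for a in angles
            ]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestFocalAdhesions:
    def test_recall_and_precision_on_phantom(self, spot_phantom, cell_mask):
        params, image, truth = spot_phantom
        spots = detect_focal_adhesions(image, cell_mask, sigma_um=0.5)
        gt = np.column_stack([truth.x_um, truth.y_um])
        tol = 2 * params.spot_sigma_um
        d_gt, _ = cKDTree(spots.centers_um).query(gt)
        d_det, _ = cKDTree(gt).query(spots.centers_um)
        assert (d_gt < tol).mean() >= 0.95  # recall
        assert (d_det < tol).mean() >= 0.95  # precision

    def test_zero_spot_image_yields_zero_detections(self, cell_mask):
        params = SpotFieldParams(n_spots=0, noise_sd=10.0)
        image, _ = generate_spot_image(params, cell_mask, seed=3)
        assert detect_focal_adhesions(image, cell_mask, sigma_um=0.5).count == 0

    def test_count_robust_to_doubled_amplitude(self, cell_mask):
        base = SpotFieldParams(n_spots=50, spot_amplitude=100.0, noise_sd=10.0)
        bright = SpotFieldParams(n_spots=50, spot_amplitude=200.0, noise_sd=10.0)
        img_a, _ = generate_spot_image(base, cell_mask, seed=4)
        img_b, _ = generate_spot_image(bright, cell_mask, seed=4)
        count_a = detect_focal_adhesions(img_a, cell_mask, sigma_um=0.5).count
        count_b = detect_focal_adhesions(img_b, cell_mask, sigma_um=0.5).count
        assert count_a == count_b

    def test_count_monotone_in_true_spot_number(self, cell_mask):
        counts = []
        for n in (10, 30, 60):
            params = SpotFieldParams(
                n_spots=n, spot_amplitude=100.0, noise_sd=10.0
            )
            image, _ = generate_spot_image(params, cell_mask, seed=4)
            counts.append(
                detect_focal_adhesions(image, cell_mask, sigma_um=0.5).count
            )
        assert counts[0] < counts[1] < counts[2]

    def test_density_uses_cell_area(self, spot_phantom, cell_mask):
        _, image, _ = spot_phantom
        spots = detect_focal_adhesions(image, cell_mask, sigma_um=0.5)
        area = cell_mask.sum() * 0.25**2
        assert spots.density_per_um2 == pytest.approx(spots.count / area)


class TestCTCF:
    def test_uniform_image_gives_zero(self, cell_mask):
        image = FiberImage(np.full(cell_mask.shape, 30.0), 0.25)
        assert ctcf(image, cell_mask, ~cell_mask).ctcf == pytest.approx(0.0)

    def test_constant_excess_gives_c_times_area(self, cell_mask):
        c = 7.0
        pixels = np.full(cell_mask.shape, 30.0)
        pixels[cell_mask] += c
        image = FiberImage(pixels, 0.25)
        result = ctcf(image, cell_mask, ~cell_mask)
        assert result.ctcf == pytest.approx(c * cell_mask.sum())

    def test_offset_invariance(self, cell_mask):
        rng = np.random.default_rng(5)
        base = rng.normal(50, 5, cell_mask.shape)
        a = ctcf(FiberImage(base, 0.25), cell_mask, ~cell_mask).ctcf
        b = ctcf(FiberImage(base + 111.0, 0.25), cell_mask, ~cell_mask).ctcf
        assert a == pytest.approx(b, abs=1e-6 * abs(a) + 1e-3)

    def test_recovers_injected_signal_within_tolerance(self, cell_mask):
        errs = []
        injected = 20.0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pixels = rng.normal(50, 5, cell_mask.shape)
            pixels[cell_mask] += injected
            res = ctcf(FiberImage(pixels.clip(0), 0.25), cell_mask, ~cell_mask)
            errs.append(res.ctcf / (injected * cell_mask.sum()) - 1)
        assert np.max(np.abs(errs)) < 0.05

    def test_overlapping_masks_rejected(self, cell_mask):
        image = FiberImage(np.ones(cell_mask.shape), 0.25)
        with pytest.raises(ValueError, match="disjoint"):
            ctcf(image, cell_mask, cell_mask)

    def test_on_off_ratio(self, cell_mask):
        pixels = np.full(cell_mask.shape, 10.0)
        pixels[cell_mask] += 8.0
        on = ctcf(FiberImage(pixels, 0.25), cell_mask, ~cell_mask)
        half = np.full(cell_mask.shape, 10.0)
        half[cell_mask] += 4.0
        off = ctcf(FiberImage(half, 0.25), cell_mask, ~cell_mask)
        assert ctcf_ratio(on, off) == pytest.approx(2.0)
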