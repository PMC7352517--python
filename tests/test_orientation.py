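"""Circular/axial statistics and structure-tensor orientation."""

import numpy as np
import pytest
from scipy.special import i0, i1

from stromascan import (
    FiberImage,
    alignment_index,
    angular_distribution,
    mean_direction,
    orientation_field,
    pearson_between,
    watson_u2,
)


def _weighted_axial_mean(field, select):
    w = field.coherence[select]
    z = np.sum(w * np.exp(2j * np.deg2rad(field.angle_deg[select])))
    return np.rad2deg(np.angle(z)) / 2 % 180


class TestOrientationField:
    def test_single_fiber_angle_recovered(self, single_fiber_image):
        image, truth = single_fiber_image
        field = orientation_field(image, sigma_um=1.0)
        on_fiber = image.pixels > 0.2 * image.pixels.max()
        recovered = _weighted_axial_mean(field, on_fiber)
        expected = truth.fiber_angle_deg.iloc[0]
        assert abs(recovered - expected) < 2.0

    def test_rotation_equivariance(self, single_fiber_image):
        image, _ = single_fiber_image
        field = orientation_field(image, sigma_um=1.0)
        sel = image.pixels > 0.2 * image.pixels.max()
        base = _weighted_axial_mean(field, sel)
        rotated = FiberImage(np.rot90(image.pixels).copy(), image.pixel_size_um)
        field_r = orientation_field(rotated, sigma_um=1.0)
        sel_r = rotated.pixels > 0.2 * rotated.pixels.max()
        rec = _weighted_axial_mean(field_r, sel_r)
        assert abs((rec - base) % 180 - 90) < 2.0

    def test_isotropic_noise_has_low_coherence(self):
        rng = np.random.default_rng(0)
        noise = FiberImage(rng.normal(100, 10, (200, 200)).clip(0), 0.5)
        field = orientation_field(noise, sigma_um=2.0)
        assert field.coherence.mean() < 0.2

    def test_constant_image_flagged_degenerate(self):
        field = orientation_field(FiberImage(np.full((32, 32), 3.0), 0.5), 1.0)
        assert field.degenerate
        assert not field.coherence.any()
        assert not field.angle_deg.any()


class TestAngularDistribution:
    def test_delta_sample_occupies_single_bin(self):
        dist = angular_distribution(np.full(100, 45.0), n_bins=36)
        assert dist.density.max() == pytest.approx(1.0)
        assert (dist.density > 0).sum() == 1

    def test_uniform_sample_is_flat(self):
        rng = np.random.default_rng(3)
        dist = angular_distribution(rng.uniform(0, 180, 10_000), n_bins=36)
        assert dist.density.max() <= 3 / 36
        assert dist.n_effective == 10_000

    def test_aligned_phantom_beats_isotropic_phantom(self, high_grade_phantom):
        from stromascan import discretize_fibers, generate_fiber_image
        from stromascan import morphology_preset

        hg_img, _ = high_grade_phantom
        n_img, _ = generate_fiber_image(morphology_preset("normal"), seed=7)
        ai = {}
        for name, img in (("high_grade", hg_img), ("normal", n_img)):
            field = orientation_field(img, 1.5)
            mask = discretize_fibers(img).mask
            ai[name] = alignment_index(
                angular_distribution(field, 36, mask=mask)
            )
        assert ai["high_grade"] > ai["normal"]

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="8"):
            angular_distribution(np.zeros(10), n_bins=4)


class TestAlignmentIndex:
    def test_single_bin_is_fully_aligned(self):
        dist = angular_distribution(np.full(50, 90.0), n_bins=36)
        assert alignment_index(dist) == pytest.approx(1.0, abs=1e-9)

    def test_uniform_density_is_zero(self):
        from stromascan.orientation import AngularDistribution

        dist = AngularDistribution(
            bin_edges_deg=np.linspace(0, 180, 37),
            density=np.full(36, 1 / 36),
            n_effective=36,
        )
        assert alignment_index(dist) == pytest.approx(0.0, abs=1e-12)

    def test_von_mises_sample_matches_bessel_ratio(self):
        rng = np.random.default_rng(42)
        kappa = 4.0
        angles = np.rad2deg(rng.vonmises(0.0, kappa, 20_000)) / 2 % 180
        dist = angular_distribution(angles, n_bins=36)
        expected = i1(kappa) / i0(kappa)
        assert alignment_index(dist) == pytest.approx(expected, abs=0.05)


class TestPearsonBetween:
    def test_identical_distributions_correlate_perfectly(self):
        rng = np.random.default_rng(1)
        d = angular_distribution(rng.vonmises(0, 2, 500) * 90 / np.pi % 180, 36)
        assert pearson_between(d, d) == pytest.approx(1.0)

    def test_mismatched_binning_is_error(self):
        rng = np.random.default_rng(1)
        a = angular_distribution(rng.uniform(0, 180, 100), n_bins=36)
        b = angular_distribution(rng.uniform(0, 180, 100), n_bins=18)
        with pytest.raises(ValueError, match="bin edges"):
            pearson_between(a, b)

    def test_independent_uniform_null_distribution(self):
        """|r| under the null follows the 36-point normal theory: sd 1/sqrt(35)."""
        rng = np.random.default_rng(0)
        rs = []
        for _ in range(200):
            a = angular_distribution(rng.uniform(0, 180, 10_000), 36)
            b = angular_distribution(rng.uniform(0, 180, 10_000), 36)
            rs.append(pearson_between(a, b))
        rs = np.asarray(rs)
        assert abs(rs.mean()) < 0.05
        assert np.quantile(np.abs(rs), 0.95) < 0.35

    def test_guided_headings_track_fiber_distribution(
        self, high_grade_phantom, constant_axis_field
    ):
        """Contact-guided step headings correlate with the fiber distribution
        more strongly than unguided ones (stress-fiber/collagen analogue)."""
        from stromascan import (
            PRWParams,
            discretize_fibers,
            generate_trajectories,
            step_directions,
        )

        image, _ = high_grade_phantom
        field = orientation_field(image, 1.5)
        fiber_dist = angular_distribution(
            field, 36, mask=discretize_fibers(image).mask
        )
        corrs = {}
        for g in (0.0, 0.9):
            params = PRWParams(n_cells=100, n_frames=60, guidance_strength=g)
            tracks = generate_trajectories(
                params, seed=5,
                orientation_field=constant_axis_field if g > 0 else None,
            )
            headings = np.concatenate(
                [step_directions(t, axial=True)
                 for _, t in tracks.groupby("track_id")]
            )
            corrs[g] = pearson_between(
                fiber_dist, angular_distribution(headings, 36)
            )
        assert corrs[0.9] > corrs[0.0]


class TestWatsonU2:
    def test_identical_samples_not_rejected(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 180, 50)
        result = watson_u2(a, a, n_permutations=499, seed=1)
        assert result.p_value > 0.5
        assert result.u2 < 0.05

    def test_rotation_invariance_of_statistic(self):
        rng = np.random.default_rng(4)
        a = rng.vonmises(0, 2, 40) * 90 / np.pi % 180
        b = rng.vonmises(1, 2, 40) * 90 / np.pi % 180
        u1 = watson_u2(a, b, n_permutations=9, seed=0).u2
        u2 = watson_u2((a + 30) % 180, (b + 30) % 180,
                       n_permutations=9, seed=0).u2
        assert u1 == pytest.approx(u2, abs=1e-10)

    def test_power_against_perpendicular_alignment(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 40
        for i in range(n_rep):
            a = np.rad2deg(rng.vonmises(0, 4, 50)) / 2 % 180
            b = np.rad2deg(rng.vonmises(np.pi, 4, 50)) / 2 % 180
            res = watson_u2(a, b, n_permutations=199, seed=i)
            rejections += res.p_value < 0.05
        assert rejections / n_rep > 0.9

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            watson_u2(np.arange(5), np.arange(20), 99)


class TestMeanDirection:
    def test_constant_sample(self):
        assert mean_direction([30.0, 30.0, 30.0]) == pytest.approx(30.0)

    def test_axial_wraparound(self):
        assert mean_direction([10.0, 170.0]) == pytest.approx(0.0, abs=1e-9)

    def test_von_mises_consistency(self):
        rng = np.random.default_rng(11)
        angles = np.rad2deg(rng.vonmises(np.deg2rad(120.0), 4.0, 1000)) / 2 % 180
        assert mean_direction(angles) == pytest.approx(60.0, abs=2.0)

    @pytest.mark.parametrize("shift", [180.0, 360.0, 540.0])
    def test_statistics_invariant_under_axial_period(self, shift):
        rng = np.random.default_rng(2)
        a = rng.vonmises(0.5, 3, 60) * 90 / np.pi % 180
        b = rng.vonmises(1.5, 3, 60) * 90 / np.pi % 180
        assert mean_direction(a + shift) == pytest.approx(
            mean_direction(a), abs=1e-8
        )
        u_ref = watson_u2(a, b, n_permutations=9, seed=3).u2
        u_shift = watson_u2(a + shift, b, n_permutations=9, seed=3).u2
        assert u_shift == pytest.approx(u_ref, abs=1e-10)
        d_ref = angular_distribution(a, 36).density
        d_shift = angular_distribution(a + shift, 36).density
        assert np.allclose(d_ref, d_shift)
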