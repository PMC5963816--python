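"""Gradient fields, circular correlation, and the material analysis."""

import math

import numpy as np
import pytest

from gradorder import (CorrelationRecord, IntensityImage, InvalidParameterError,
                       LightConfig, MaterialParams, UndefinedStatisticError,
                       circular_correlation, correlation_density,
                       cross_light_correlation, gradient_field,
                       mask_small_gradients, pairwise_material_correlations,
                       render_asperity, render_lambert)
from gradorder.gradients import direction_agreement


def _ramp(k, angle_rad, n=32):
    """Linear ramp of slope k whose gradient points along angle_rad."""
    x = np.arange(n) + 0.5
    y = n - np.arange(n) - 0.5  # y up
    u, v = np.meshgrid(x, y)
    vals = k * (u * math.cos(angle_rad) + v * math.sin(angle_rad))
    vals -= vals.min()
    return IntensityImage(np.clip(vals, 0.0, 1.0), np.ones((n, n), bool))


class TestGradientField:
    def test_constant_image_has_zero_magnitude(self):
        img = IntensityImage(np.full((16, 16), 0.5), np.ones((16, 16), bool))
        gf = gradient_field(img)
        assert np.all(gf.magnitude[gf.mask] == 0.0)

    def test_horizontal_ramp_points_right(self):
        gf = gradient_field(_ramp(0.01, 0.0))
        d = gf.direction[gf.mask]
        assert np.allclose(np.abs(d), 0.0, atol=1e-9)
        mags = gf.magnitude[gf.mask]
        assert np.ptp(mags) < 1e-12

    def test_diagonal_ramp_direction_is_pi_over_4(self):
        gf = gradient_field(_ramp(0.01, math.pi / 4))
        assert np.allclose(gf.direction[gf.mask], math.pi / 4, atol=1e-6)

    def test_vertical_ramp_points_up(self):
        gf = gradient_field(_ramp(0.01, math.pi / 2))
        assert np.allclose(gf.direction[gf.mask], math.pi / 2, atol=1e-9)

    def test_border_exclusion_modes(self):
        img = IntensityImage(np.random.default_rng(0).random((16, 16)),
                             np.ones((16, 16), bool))
        assert gradient_field(img, exclude_border=True).mask.sum() == 12 * 12
        assert gradient_field(img, exclude_border=False).mask.all()

    def test_silhouette_rim_always_excluded(self, bumpy_sphere, frontal_light):
        img = render_lambert(bumpy_sphere, frontal_light, rho_d=0.6)
        gf = gradient_field(img, exclude_border=False)
        assert gf.mask.sum() < bumpy_sphere.mask.sum()
        assert not gf.mask[~bumpy_sphere.mask].any()

    def test_too_small_image_rejected(self):
        img = IntensityImage(np.zeros((4, 4)), np.ones((4, 4), bool))
        with pytest.raises(InvalidParameterError):
            gradient_field(img)


class TestMaskSmallGradients:
    def test_zero_threshold_keeps_mask(self):
        gf = gradient_field(_ramp(0.01, 0.0))
        assert np.array_equal(mask_small_gradients(gf, 0.0).mask, gf.mask)

    def test_constant_image_fully_excluded(self):
        img = IntensityImage(np.full((16, 16), 0.5), np.ones((16, 16), bool))
        gf = mask_small_gradients(gradient_field(img), 0.0002)
        assert not gf.mask.any()

    def test_threshold_brackets_ramp_slope(self):
        weak = mask_small_gradients(gradient_field(_ramp(0.0001, 0.0)), 0.0002)
        assert not weak.mask.any()
        strong = gradient_field(_ramp(0.001, 0.0))
        kept = mask_small_gradients(strong, 0.0002)
        assert np.array_equal(kept.mask, strong.mask)


class TestCircularCorrelation:
    def test_self_correlation_is_one(self):
        a = np.random.default_rng(0).uniform(-math.pi, math.pi, 500)
        for method in ("mean", "pairwise"):
            assert circular_correlation(a, a, method=method) == pytest.approx(1.0)

    def test_invariant_to_constant_rotation(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.5, 0.8, 400)
        for method in ("mean", "pairwise"):
            r0 = circular_correlation(a, a + 1.2, method=method)
            assert r0 == pytest.approx(1.0, abs=1e-9)

    def test_mirrored_angles_anticorrelate(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.0, 0.7, 1000)
        assert circular_correlation(a, -a) == pytest.approx(-1.0, abs=0.05)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(-math.pi, math.pi, 1000)
        b = a + rng.normal(0.0, 0.3, 1000)
        abar = math.atan2(np.sin(a).mean(), np.cos(a).mean())
        bbar = math.atan2(np.sin(b).mean(), np.cos(b).mean())
        num = sum(math.sin(x - abar) * math.sin(y - bbar) for x, y in zip(a, b))
        den = math.sqrt(sum(math.sin(x - abar) ** 2 for x in a)
                        * sum(math.sin(y - bbar) ** 2 for y in b))
        assert circular_correlation(a, b) == pytest.approx(num / den, abs=1e-12)

    def test_matches_independent_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 2 * math.pi, 300)
        b = np.mod(a + rng.normal(0, 0.5, 300), 2 * math.pi)
        r_ref, _ = pingouin.circ_corrcc(a, b)
        assert circular_correlation(a, b) == pytest.approx(float(r_ref), abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            circular_correlation([0.5] * 10, list(np.linspace(0, 3, 10)))

    def test_direction_agreement_detects_flip(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(-math.pi, math.pi, 500)
        assert direction_agreement(a, a + math.pi) == pytest.approx(-1.0, abs=1e-12)
        # a whole-map flip is invisible to any rotation-invariant correlation
        assert circular_correlation(a, a + math.pi) == pytest.approx(1.0, abs=1e-9)


class TestPairwiseMaterialCorrelations:
    def test_material_with_itself_scores_one(self, bandpass_geometries, frontal_light):
        mat = MaterialParams.lambertian()
        recs = pairwise_material_correlations([mat], bandpass_geometries, frontal_light)
        assert len(recs) == 1
        assert recs[0].dir_corr == 1.0 and recs[0].mag_corr == 1.0

    def test_full_frame_pooling_counts_every_pixel(self, bandpass_geometries,
                                                   frontal_light):
        mats = [MaterialParams.lambertian(), MaterialParams.ward()]
        recs = pairwise_material_correlations(mats, bandpass_geometries, frontal_light,
                                              threshold=None, exclude_border=False)
        assert recs[0].n_pixels == 3 * 64 * 64

    def test_direction_more_stable_than_magnitude(self, bandpass_geometries,
                                                  frontal_light):
        mats = [MaterialParams.lambertian(rho_d=0.5), MaterialParams.ward()]
        rec = pairwise_material_correlations(mats, bandpass_geometries,
                                             frontal_light)[0]
        assert rec.dir_corr > rec.mag_corr
        assert rec.dir_corr > 0.9

    def test_cross_illumination_degrades_direction(self, bandpass_geometries):
        mat = MaterialParams.lambertian()
        rec = cross_light_correlation(mat, bandpass_geometries,
                                      LightConfig(0.0), LightConfig(40.0))
        within = pairwise_material_correlations(
            [mat, MaterialParams.ward()], bandpass_geometries, LightConfig(0.0))[0]
        assert rec.dir_corr < within.dir_corr

    def test_asperity_reversal_flips_directions(self, bandpass_geometries,
                                                frontal_light):
        lam = render_lambert(bandpass_geometries[0], frontal_light, 0.6, math.pi)
        asp = render_asperity(bandpass_geometries[0], frontal_light, 0.02,
                              4 * math.pi)
        gl, ga = gradient_field(lam), gradient_field(asp)
        nz = bandpass_geometries[0].normals[..., 2]
        reversed_range = gl.mask & ga.mask & (nz > math.sqrt(0.02) + 0.05)
        agree = direction_agreement(gl.direction[reversed_range],
                                    ga.direction[reversed_range])
        assert agree < -0.9


class TestCorrelationDensity:
    def test_single_record_concentrates_in_one_bin(self):
        rec = CorrelationRecord("a", "b", 0.95, 0.10, 100)
        df = correlation_density([rec], n_bins=10)
        widths = df.bin_right - df.bin_left
        assert (df.dir_density * widths).sum() == pytest.approx(1.0)
        assert (df.dir_density > 0).sum() == 1
        assert df.bin_left[df.dir_density.idxmax()] <= 0.95 <= df.bin_right[
            df.dir_density.idxmax()]

    def test_perfect_correlations_fill_top_bin(self):
        recs = [CorrelationRecord("a", "b", 1.0, 1.0, 10)] * 5
        df = correlation_density(recs, n_bins=4)
        assert df.dir_density.iloc[-1] > 0
        assert (df.dir_density.iloc[:-1] == 0).all()

    def test_uniform_records_give_flat_density(self):
        rng = np.random.default_rng(9)
        recs = [CorrelationRecord("a", "b", r, r, 10)
                for r in rng.uniform(0.0, 1.0, 4000)]
        df = correlation_density(recs, n_bins=4)
        top = df[df.bin_left >= 0.0]
        assert np.allclose(top.dir_density, 1.0, atol=0.1)
        assert np.allclose(df[df.bin_right <= 0.0].dir_density, 0.0)
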