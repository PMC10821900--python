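"""Detection, unmixing and per-field quantification against ground truth."""

import dataclasses

import numpy as np
import pytest

from conftest import match_points
from oracles import flood_fill_count
from skinquant import (
    FieldParams,
    SpotConfig,
    UnmixModel,
    WholemountConfig,
    detect_follicles,
    detect_mcsc_spots,
    estimate_bleed,
    generate_wholemount,
    quantify_field,
    unmix_green,
)
from skinquant._errors import DegenerateFitError, InsufficientDataError
from skinquant.simulate import _paint_spots


class TestFollicleDetection:
    def test_exact_count_on_noise_free_field(self, noisefree_field):
        field, truth = noisefree_field
        det = detect_follicles(field.red)
        assert det.count == truth.n_follicles

    def test_count_on_default_noise_field(self, small_field):
        field, truth = small_field
        det = detect_follicles(field.red)
        assert abs(det.count - truth.n_follicles) <= 0.05 * truth.n_follicles

    def test_all_zero_image_flags_low_contrast(self):
        det = detect_follicles(np.zeros((64, 64)))
        assert det.count == 0 and "low_contrast" in det.flags

    def test_centroids_match_truth(self, noisefree_field):
        field, truth = noisefree_field
        det = detect_follicles(field.red)
        n, rms = match_points(det.centroids, truth.follicle_centers, gate_px=3.0)
        assert n == truth.n_follicles and rms < 1.0

    def test_component_count_equals_flood_fill_oracle(self):
        """The labelling stage agrees with an independent BFS flood fill on
        small fields (<= 30 follicles)."""
        for seed in range(3):
            p = FieldParams(width_px=512, height_px=512, n_follicles=25,
                            noise_sd=0.0, seed=seed)
            field, _ = generate_wholemount(p)
            det = detect_follicles(field.red)
            assert det.count == flood_fill_count(det.mask)

    def test_roi_validation(self):
        from skinquant._errors import ValidationError
        from skinquant import FollicleConfig
        with pytest.raises(ValidationError):
            detect_follicles(np.ones((32, 32)),
                             FollicleConfig(roi=(0, 0, 64, 64)))


class TestBleedEstimation:
    def test_recovers_generator_alpha(self, small_params):
        p = dataclasses.replace(small_params, bleed_alpha=0.30, seed=11)
        field, truth = generate_wholemount(p)
        det = detect_follicles(field.red)
        from scipy import ndimage as ndi
        mask = ndi.binary_dilation(det.mask, iterations=3)
        model = estimate_bleed(field.red, field.green, mask)
        assert abs(model.alpha - 0.30) <= 0.02

    def test_identity_channels(self):
        rng = np.random.default_rng(0)
        red = rng.uniform(10, 1000, size=(64, 64))
        model = estimate_bleed(red, red, np.ones_like(red, dtype=bool))
        assert model.alpha == pytest.approx(1.0, abs=1e-9)
        assert model.intercept == pytest.approx(0.0, abs=1e-6)

    def test_constant_green(self):
        rng = np.random.default_rng(1)
        red = rng.uniform(10, 1000, size=(64, 64))
        green = np.full_like(red, 42.0)
        model = estimate_bleed(red, green, np.ones_like(red, dtype=bool))
        assert model.alpha == pytest.approx(0.0, abs=1e-12)
        assert model.intercept == pytest.approx(42.0, abs=1e-9)

    def test_lad_agrees_with_theil_sen(self):
        from skinquant import BleedConfig
        rng = np.random.default_rng(2)
        red = rng.uniform(0, 1000, size=(128, 128))
        green = 0.3 * red + 5 + rng.normal(0, 3, red.shape)
        mask = np.ones_like(red, dtype=bool)
        m1 = estimate_bleed(red, np.clip(green, 0, None), mask,
                            BleedConfig(method="theil_sen"))
        m2 = estimate_bleed(red, np.clip(green, 0, None), mask,
                            BleedConfig(method="lad"))
        assert abs(m1.alpha - m2.alpha) < 0.01

    def test_degenerate_inputs_raise(self):
        flat = np.full((64, 64), 7.0)
        with pytest.raises(DegenerateFitError):
            estimate_bleed(flat, flat, np.ones_like(flat, dtype=bool))
        with pytest.raises(InsufficientDataError):
            estimate_bleed(flat, flat, np.zeros_like(flat, dtype=bool))


class TestUnmix:
    def test_exact_cancellation(self):
        rng = np.random.default_rng(3)
        red = rng.uniform(0, 100, size=(32, 32))
        green = 0.3 * red + 5.0
        out = unmix_green(green, red, UnmixModel(0.3, 5.0, 0, 0.0))
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_identity_model(self):
        rng = np.random.default_rng(4)
        green = rng.uniform(0, 100, size=(32, 32))
        out = unmix_green(green, np.zeros_like(green),
                          UnmixModel(0.0, 0.0, 0, 0.0))
        assert np.array_equal(out, green)

    def test_noise_free_residual_is_pure_spot_image(self, small_params):
        p = dataclasses.replace(small_params, noise_sd=0.0, mcsc_rate=0.5,
                                seed=21)
        field, truth = generate_wholemount(p)
        model = UnmixModel(alpha=truth.bleed_alpha,
                           intercept=p.bg_level * (1 - truth.bleed_alpha),
                           n_pixels_used=0, fit_diagnostic=0.0)
        corrected = unmix_green(field.green, field.red, model)
        spots = _paint_spots(field.shape, np.asarray(truth.mcsc_positions),
                             np.asarray(truth.mcsc_peaks), p.spot_sigma_px)
        assert np.abs(corrected - spots).max() < 1e-9


class TestSpotDetection:
    def test_noise_free_grid_of_spots_found_exactly(self):
        """40 spots on a jittered grid, separation far above min_separation:
        every one is found within 1 px."""
        rng = np.random.default_rng(7)
        xs, ys = np.meshgrid(np.arange(40, 360, 45), np.arange(40, 360, 45))
        pos = np.column_stack([xs.ravel(), ys.ravel()])[:40] \
            + rng.uniform(-3, 3, size=(40, 2))
        img = _paint_spots((400, 400), pos, np.full(40, 1000.0), 2.0)
        det = detect_mcsc_spots(img)
        assert det.count == 40
        n, rms = match_points(det.centroids, pos, gate_px=3.0)
        assert n == 40 and rms < 1.0

    def test_all_zero_image(self):
        det = detect_mcsc_spots(np.zeros((64, 64)))
        assert det.count == 0

    def test_close_pair_suppressed_to_one(self):
        cfg = SpotConfig()
        sep = 0.5 * cfg.min_separation_px
        pos = np.array([[50.0, 50.0], [50.0 + sep, 50.0]])
        img = _paint_spots((100, 100), pos, np.array([1000.0, 900.0]), 2.0)
        det = detect_mcsc_spots(img, cfg)
        assert det.count == 1

    def test_false_positive_rate_on_spotless_fields(self):
        fps = []
        for seed in range(20):
            p = FieldParams(width_px=512, height_px=512, n_follicles=20,
                            mcsc_rate=0.0, seed=seed)
            field, _ = generate_wholemount(p)
            fps.append(quantify_field(field).record.n_mcsc)
        assert np.mean(fps) <= 1.0

    def test_counts_invariant_to_global_rescaling(self, small_field):
        field, _ = small_field
        q1 = quantify_field(field)
        scaled = dataclasses.replace(field, green=field.green * 3.7,
                                     red=field.red * 3.7)
        q2 = quantify_field(scaled)
        assert q1.record.n_follicles == q2.record.n_follicles
        assert q1.record.n_mcsc == q2.record.n_mcsc


class TestQuantifyField:
    def test_end_to_end_counts_match_truth(self, small_field):
        field, truth = small_field
        q = quantify_field(field)
        assert abs(q.record.n_follicles - truth.n_follicles) \
            <= max(1, 0.05 * truth.n_follicles)
        n_match, _ = match_points([c for c in q.spots.centroids],
                                  truth.mcsc_positions, gate_px=3.0)
        tp = n_match
        fp = q.record.n_mcsc - tp
        fn = truth.n_mcsc - tp
        f1 = 2 * tp / (2 * tp + fp + fn) if truth.n_mcsc else 1.0
        assert f1 >= 0.95
        assert abs(q.unmix.alpha - truth.bleed_alpha) <= 0.02

    def test_all_zero_field_returns_zero_record(self):
        from skinquant import TwoChannelField
        z = np.zeros((64, 64))
        field = TwoChannelField(green=z, red=z.copy(), pixel_size_um=1.0,
                                field_id="z", mouse_id="z")
        q = quantify_field(field)
        assert q.record.n_follicles == 0 and q.record.n_mcsc == 0
        assert "low_contrast" in q.flags

    def test_detected_spot_count_monotone_in_true_rate(self):
        """Mean detected melanocyte count is non-decreasing in the true
        per-follicle rate."""
        rates = [0.25, 0.5, 1.0, 2.0]
        means = []
        for rate in rates:
            counts = []
            for seed in range(25):
                p = FieldParams(width_px=256, height_px=256, n_follicles=8,
                                mcsc_rate=rate, seed=1000 + seed)
                field, _ = generate_wholemount(p)
                counts.append(quantify_field(field).record.n_mcsc)
            means.append(np.mean(counts))
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_overlay_has_image_shape(self, small_field):
        field, _ = small_field
        q = quantify_field(field, WholemountConfig(), return_overlay=True)
        assert q.overlay.shape == (*field.shape, 3)
        assert q.overlay.dtype == np.uint8
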