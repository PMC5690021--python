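"""Weighted ZNCC, correlation surface and subpixel best match."""

import math

import numpy as np
import pytest
from scipy import ndimage

from setuperr import (
    MatchConfig,
    best_match,
    compute_sigma,
    correlation_surface,
    gaussian_weight,
    weighted_zncc,
)
from setuperr.types import MatchError

from .conftest import make_radiograph
from .oracles import zncc_oracle


class TestSigmaAndWeight:
    def test_sigma_defaults(self):
        assert compute_sigma(384, 0.4) == pytest.approx(153.6)
        assert compute_sigma(100, 1.0) == 100
        assert compute_sigma(1, 0.5) == 0.5

    def test_sigma_preconditions(self):
        with pytest.raises(ValueError):
            compute_sigma(0, 0.4)
        with pytest.raises(ValueError):
            compute_sigma(10, 0.0)

    def test_weight_unity_at_isocenter(self):
        assert gaussian_weight((10, 20), (2, -3), (12, 17), sigma=50.0) == pytest.approx(1.0)

    def test_weight_one_sigma_displacement(self):
        w = gaussian_weight((0, 0), (30.0, 0.0), (0, 0), sigma=30.0)
        assert w == pytest.approx(math.exp(-0.5))

    def test_weight_radially_symmetric(self):
        a = gaussian_weight((0, 0), (3.0, 7.0), (0, 0), sigma=11.0)
        b = gaussian_weight((0, 0), (7.0, 3.0), (0, 0), sigma=11.0)
        assert a == pytest.approx(b, rel=1e-15)

    def test_weight_requires_positive_sigma(self):
        with pytest.raises(ValueError):
            gaussian_weight((0, 0), (0, 0), (0, 0), sigma=0.0)


class TestWeightedZncc:
    def test_identity_gives_one(self, textured_pair, small_cfg):
        dr, drr = textured_pair
        assert weighted_zncc(dr, drr, (0, 0), small_cfg) == pytest.approx(1.0, abs=1e-12)

    def test_negated_reflection_gives_minus_one(self, textured_pair, small_cfg):
        # uniform-weight limit: reflection about the mean flips R exactly
        import dataclasses

        cfg = dataclasses.replace(small_cfg, s_sigma=1e9)
        dr, drr = textured_pair
        neg = make_radiograph(2 * drr.pixels.mean() - drr.pixels, "frontal")
        assert weighted_zncc(neg, drr, (0, 0), cfg) == pytest.approx(-1.0, abs=1e-9)

    def test_matches_literal_oracle(self, rng, small_cfg):
        dr = make_radiograph(rng.random((48, 48)) * 4000 + 1000)
        drr = make_radiograph(rng.random((48, 48)) * 4000 + 1000)
        N = small_cfg.N
        sigma = compute_sigma(N, small_cfg.s_sigma)
        for d in [(0, 0), (2, -3), (-1.5, 0.5), (0.25, 2.75)]:
            got = weighted_zncc(dr, drr, d, small_cfg)
            want = zncc_oracle(
                dr.pixels, drr.pixels, d, dr.isocenter_px, N, sigma,
                min_valid=small_cfg.min_valid_px,
            )
            assert got == pytest.approx(want, abs=1e-10), d

    def test_respects_valid_mask(self, rng, small_cfg):
        dr = make_radiograph(rng.random((48, 48)) * 1000)
        drr = make_radiograph(rng.random((48, 48)) * 1000)
        valid = np.ones((48, 48), bool)
        valid[:24, :] = False
        N, sigma = small_cfg.N, compute_sigma(small_cfg.N, small_cfg.s_sigma)
        got = weighted_zncc(dr, drr, (1, -1), small_cfg, valid=valid)
        want = zncc_oracle(dr.pixels, drr.pixels, (1, -1), dr.isocenter_px, N, sigma,
                           valid=valid, min_valid=small_cfg.min_valid_px)
        assert got == pytest.approx(want, abs=1e-10)

    def test_zero_variance_is_undefined(self, small_cfg, rng):
        # a constant patch stays constant only under uniform weight
        import dataclasses

        cfg = dataclasses.replace(small_cfg, s_sigma=1e9)
        flat = make_radiograph(np.full((48, 48), 500.0))
        other = make_radiograph(rng.random((48, 48)) * 1000)
        assert math.isnan(weighted_zncc(flat, other, (0, 0), cfg))
        assert math.isnan(weighted_zncc(other, flat, (0, 0), cfg))

    def test_too_few_valid_pixels_is_undefined(self, textured_pair, small_cfg):
        dr, drr = textured_pair
        valid = np.zeros((48, 48), bool)
        valid[23:26, 23:26] = True  # 9 < min_valid_px
        assert math.isnan(weighted_zncc(dr, drr, (0, 0), small_cfg, valid=valid))

    def test_gain_invariance(self, rng, small_cfg):
        dr = make_radiograph(rng.random((48, 48)) * 3000 + 500)
        drr = make_radiograph(rng.random((48, 48)) * 3000 + 500)
        r1 = weighted_zncc(dr, drr, (1, 2), small_cfg)
        scaled = make_radiograph(3.7 * drr.pixels, "frontal")
        r2 = weighted_zncc(dr, scaled, (1, 2), small_cfg)
        assert abs(r1 - r2) < 1e-9

    def test_offset_invariance_with_uniform_weight(self, rng, small_cfg):
        # sigma -> infinity limit: the weight is 1 everywhere, so adding a
        # constant to either image cancels in the zero-mean sums
        import dataclasses

        cfg = dataclasses.replace(small_cfg, s_sigma=1e9)
        dr = make_radiograph(rng.random((48, 48)) * 3000)
        drr = make_radiograph(rng.random((48, 48)) * 3000)
        r1 = weighted_zncc(dr, drr, (0, 1), cfg)
        r2 = weighted_zncc(dr, make_radiograph(drr.pixels + 12345.0), (0, 1), cfg)
        assert abs(r1 - r2) < 1e-9

    def test_bounded_in_unit_interval(self, rng, small_cfg):
        for _ in range(10):
            dr = make_radiograph(rng.random((48, 48)) * 1000)
            drr = make_radiograph(rng.random((48, 48)) * 1000)
            r = weighted_zncc(dr, drr, (rng.integers(-3, 4), rng.integers(-3, 4)), small_cfg)
            assert -1.0 <= r <= 1.0


class TestCorrelationSurface:
    def test_autocorrelation_peaks_at_origin(self, textured_pair, small_cfg):
        dr, drr = textured_pair
        surf = correlation_surface(dr, drr, small_cfg)
        dx, dy, r = surf.argmax()
        assert (dx, dy) == (0, 0)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_integer_shift_is_recovered(self, rng, small_cfg):
        base = ndimage.gaussian_filter(rng.normal(0, 1, (64, 64)), 1.5) * 5000 + 20000
        drr = make_radiograph(base)
        # DR content moved by (+3, -2): DR(p) = DRR(p - t) => peak at d = (-3, +2)
        dr = make_radiograph(np.roll(np.roll(base, 3, axis=1), -2, axis=0))
        surf = correlation_surface(dr, drr, small_cfg)
        dx, dy, _ = surf.argmax()
        assert (dx, dy) == (-3, 2)

    def test_every_finite_entry_in_unit_interval(self, rng, small_cfg):
        dr = make_radiograph(rng.random((48, 48)) * 900)
        drr = make_radiograph(rng.random((48, 48)) * 900)
        surf = correlation_surface(dr, drr, small_cfg)
        finite = surf.values[np.isfinite(surf.values)]
        assert finite.size and (finite >= -1).all() and (finite <= 1).all()

    def test_surface_spans_centered_grid(self, textured_pair, small_cfg):
        dr, drr = textured_pair
        surf = correlation_surface(dr, drr, small_cfg)
        assert surf.values.shape == (small_cfg.M, small_cfg.M)
        assert surf.dx_offsets[0] == -(small_cfg.M // 2)
        assert surf.dx_offsets[-1] == small_cfg.M - small_cfg.M // 2 - 1

    def test_all_undefined_raises(self, small_cfg, rng):
        import dataclasses

        cfg = dataclasses.replace(small_cfg, s_sigma=1e9)
        flat = make_radiograph(np.full((48, 48), 100.0))
        other = make_radiograph(rng.random((48, 48)))
        with pytest.raises(MatchError):
            correlation_surface(flat, other, cfg)


class TestBestMatch:
    def test_identity(self, textured_pair, small_cfg):
        dr, drr = textured_pair
        disp = best_match(dr, drr, small_cfg)
        assert (disp.dx_px, disp.dy_px) == (0.0, 0.0)
        assert disp.peak_correlation == pytest.approx(1.0, abs=1e-12)
        assert not disp.at_search_border

    def test_fractional_shift_recovered(self, rng, small_cfg):
        base = ndimage.gaussian_filter(rng.normal(0, 1, (64, 64)), 2.0) * 5000 + 20000
        drr = make_radiograph(base)
        # content moved by (tx, ty) = (1.5, -0.5); the matcher reports -t
        shifted = ndimage.shift(base, (-0.5, 1.5), order=1, mode="nearest")
        dr = make_radiograph(shifted)
        import dataclasses

        cfg = dataclasses.replace(small_cfg, subpixel_step_px=0.05)
        disp = best_match(dr, drr, cfg)
        assert disp.dx_px == pytest.approx(-1.5, abs=0.1)
        assert disp.dy_px == pytest.approx(0.5, abs=0.1)

    def test_refined_peak_not_below_integer_peak(self, rng, small_cfg):
        dr = make_radiograph(ndimage.gaussian_filter(rng.normal(0, 1, (48, 48)), 1.0) * 900)
        drr = make_radiograph(ndimage.gaussian_filter(rng.normal(0, 1, (48, 48)), 1.0) * 900)
        surf = correlation_surface(dr, drr, small_cfg)
        _, _, r_int = surf.argmax()
        disp = best_match(dr, drr, small_cfg)
        assert disp.peak_correlation >= r_int - 1e-9

    def test_shift_consistency(self, rng, small_cfg):
        base = ndimage.gaussian_filter(rng.normal(0, 1, (64, 64)), 2.0) * 4000 + 15000
        a = make_radiograph(base)
        v = (2.0, -1.0)
        moved = make_radiograph(ndimage.shift(base, (v[1], v[0]), order=1, mode="nearest"))
        fwd = best_match(moved, a, small_cfg)
        rev = best_match(a, moved, small_cfg)
        tol = 2 * small_cfg.subpixel_step_px
        assert fwd.dx_px == pytest.approx(-rev.dx_px, abs=tol)
        assert fwd.dy_px == pytest.approx(-rev.dy_px, abs=tol)

    def test_border_peak_flagged(self, rng, small_cfg):
        base = ndimage.gaussian_filter(rng.normal(0, 1, (64, 64)), 2.0) * 4000 + 15000
        drr = make_radiograph(base)
        # content shift (M/2 + 2) px exceeds the search range
        t = small_cfg.M // 2 + 2
        dr = make_radiograph(np.roll(base, t, axis=1))
        disp = best_match(dr, drr, small_cfg)
        assert disp.at_search_border

    def test_deterministic(self, textured_pair, small_cfg):
        dr, drr = textured_pair
        a = best_match(dr, drr, small_cfg)
        b = best_match(dr, drr, small_cfg)
        assert a == b
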