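"""Control-point detector: per-slice steps and volume-level extraction."""

import logging

import numpy as np
import pytest
from scipy import ndimage

from mrdistcorr import (
    DetectionParams,
    Volume,
    adaptive_threshold,
    dot_centroids,
    extract_control_points,
    invert_if_mr,
    line_intersection_mask,
    separate_and_filter_dots,
    unsharp_mask,
)
from conftest import MINI_NOISE, nearest_errors


def synth_grid_slice(n=140, pitch=15, bar=2, lines=5, level=900.0):
    """Noise-free two-level grid image (bright bars on zero background)."""
    img = np.zeros((n, n))
    c = n // 2
    offs = (np.arange(lines) - (lines - 1) / 2) * pitch
    half_len = (lines - 1) / 2 * pitch + pitch
    for o in offs:
        i = int(round(c + o))
        lo, hi = int(c - half_len), int(c + half_len)
        img[i - bar // 2 : i + bar // 2 + 1, lo:hi] = level
        img[lo:hi, i - bar // 2 : i + bar // 2 + 1] = level
    return img


class TestInvert:
    def test_ct_unchanged(self, mini_ct):
        assert invert_if_mr(mini_ct) is mini_ct

    def test_constant_mr_becomes_zero(self):
        v = Volume(np.full((8, 8, 8), 7.0, np.float32), (1, 1, 1), modality="MR")
        assert np.all(invert_if_mr(v).data == 0)

    def test_involution_up_to_constant(self, mini_mr):
        once = invert_if_mr(mini_mr)
        twice = invert_if_mr(once)
        diff = twice.data.astype(float) - mini_mr.data
        assert np.allclose(diff, diff.ravel()[0])


class TestUnsharp:
    def test_constant_image_zero(self):
        out = unsharp_mask(np.full((64, 64), 5.0), 20.0, (1.0, 1.0))
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_grid_slice_mean_near_zero(self):
        img = synth_grid_slice()
        out = unsharp_mask(img, 45.0, (1.0, 1.0))
        assert abs(out.mean()) < 0.02 * img.max()


class TestAdaptiveThreshold:
    def test_two_level_grid_mask_is_grid_support(self):
        img = synth_grid_slice()
        u = unsharp_mask(img, 45.0, (1.0, 1.0))
        mask = adaptive_threshold(u)
        assert np.array_equal(mask, img > 0)

    def test_scale_invariance(self):
        img = synth_grid_slice()
        u = unsharp_mask(img, 45.0, (1.0, 1.0))
        assert np.array_equal(adaptive_threshold(u), adaptive_threshold(2.0 * u))

    def test_zero_dynamic_range_warns_and_empties(self, caplog):
        with caplog.at_level(logging.WARNING, logger="mrdistcorr.detect"):
            mask = adaptive_threshold(np.zeros((32, 32)))
        assert not mask.any()
        assert "zero dynamic range" in caplog.text


class TestLineIntersectionMask:
    def test_single_cross_yields_single_dot(self):
        img = np.zeros((120, 120))
        img[59:61, 20:100] = 900.0
        img[20:100, 59:61] = 900.0
        mask = img > 0
        dots = line_intersection_mask(mask, 5.0, (1.0, 1.0), intensity_image=img)
        labels, n = ndimage.label(dots > 0)
        assert n == 1
        com = ndimage.center_of_mass(dots)
        assert abs(com[0] - 59.5) < 1 and abs(com[1] - 59.5) < 1

    def test_full_grid_yields_all_crossings(self):
        img = synth_grid_slice()
        u = unsharp_mask(img, 45.0, (1.0, 1.0))
        dots = line_intersection_mask(adaptive_threshold(u), 5.0, (1.0, 1.0), intensity_image=u)
        _, n = ndimage.label(dots > 0)
        assert n == 25

    def test_isolated_disc_suppressed(self):
        img = synth_grid_slice()
        # dot-sized bubble in a cell center, away from all lines
        yy, xx = np.mgrid[:140, :140]
        disc = (xx - 77.5) ** 2 + (yy - 77.5) ** 2 <= 2.5**2
        img[disc] = 1000.0
        u = unsharp_mask(img, 45.0, (1.0, 1.0))
        dots = line_intersection_mask(adaptive_threshold(u), 5.0, (1.0, 1.0), intensity_image=u)
        labels, n = ndimage.label(dots > 0)
        assert n == 25  # the disc adds no dot
        assert dots[72:83, 72:83].max() == 0.0


class TestSeparateAndFilter:
    def test_twin_dots_split_by_watershed(self):
        # two dots 1.5 mm apart at 0.5 mm pixels: merged support, two peaks
        yy, xx = np.mgrid[:60, :60]
        img = np.exp(-((xx - 28.0) ** 2 + (yy - 30) ** 2) / 2.9)
        img += np.exp(-((xx - 31.0) ** 2 + (yy - 30) ** 2) / 2.9)
        img[img < 0.2] = 0.0
        assert ndimage.label(img > 0)[1] == 1  # single connected support
        params = DetectionParams(area_min_px=2, area_max_px=400, expected_dot_px=20)
        labels = separate_and_filter_dots(img, params.resolved((0.5, 0.5)))
        assert labels.max() == 2

    def test_oversize_region_discarded(self):
        # one smooth 200-px blob, far larger than any plausible dot
        yy, xx = np.mgrid[:64, :64]
        img = np.exp(-((xx - 32) ** 2 / 120.0 + (yy - 32) ** 2 / 30.0))
        img[img < np.sort(img.ravel())[-200]] = 0.0
        params = DetectionParams(area_min_px=3, area_max_px=60, expected_dot_px=15)
        labels = separate_and_filter_dots(img, params.resolved((1.0, 1.0)))
        assert labels.max() == 0


class TestDotCentroids:
    def test_symmetric_gaussian_centroid(self):
        yy, xx = np.mgrid[:40, :40]
        w = np.exp(-((xx - 20.0) ** 2 + (yy - 10.0) ** 2) / 6.0)
        labels = (w > 0.05).astype(np.int32)
        df = dot_centroids(labels, w, (0.0, 0.0), (1.0, 1.0))
        assert df["u_mm"].iloc[0] == pytest.approx(10.0, abs=0.05)
        assert df["v_mm"].iloc[0] == pytest.approx(20.0, abs=0.05)

    def test_linear_ramp_shifts_by_first_moment(self):
        # uniform 5x5 square with linear weight ramp: centroid = weighted mean
        w = np.zeros((20, 20))
        ramp = np.arange(5) + 1.0
        w[8:13, 8:13] = ramp[None, :]
        labels = (w > 0).astype(np.int32)
        df = dot_centroids(labels, w, (0.0, 0.0), (1.0, 1.0))
        expect_v = np.sum((np.arange(8, 13)) * ramp) / ramp.sum()
        assert df["v_mm"].iloc[0] == pytest.approx(expect_v, abs=1e-9)
        assert df["u_mm"].iloc[0] == pytest.approx(10.0, abs=1e-9)


class TestExtraction:
    def test_clean_phantom_exact_count_subvoxel(self, mini_geo, mini_mr_points, mini_nominal):
        assert len(mini_mr_points) == mini_geo.n_points
        assert nearest_errors(mini_mr_points.coords, mini_nominal).max() < 0.5

    def test_degraded_phantom_within_one_voxel(self, mini_geo, mini_mr_degraded, mini_nominal):
        cps = extract_control_points(mini_mr_degraded)
        assert len(cps) == mini_geo.n_points
        assert nearest_errors(cps.coords, mini_nominal).max() < 1.0

    def test_global_intensity_scaling_invariance(self, mini_mr, mini_mr_points):
        scaled = mini_mr.copy_with((mini_mr.data * 2.5).astype(np.float32))
        cps = extract_control_points(scaled)
        assert len(cps) == len(mini_mr_points)
        assert nearest_errors(cps.coords, mini_mr_points.coords).max() < 1e-6

    def test_empty_volume_warns(self, caplog):
        v = Volume(np.full((40, 40, 30), 1000.0, np.float32), (2, 2, 2), modality="MR")
        with caplog.at_level(logging.WARNING, logger="mrdistcorr.detect"):
            cps = extract_control_points(v)
        assert len(cps) == 0

    def test_ct_streak_removed(self, mini_geo, mini_ct, mini_nominal):
        """A bright couch/frame-like streak across the CT volume must not
        survive into the point set."""
        data = mini_ct.data.copy()
        i0 = 10  # streak near the volume edge, spanning the full width
        data[:, i0 : i0 + 10, :] = np.maximum(data[:, i0 : i0 + 10, :], 900.0)
        streaked = mini_ct.copy_with(data)
        cps = extract_control_points(streaked)
        assert len(cps) == mini_geo.n_points
        assert nearest_errors(cps.coords, mini_nominal).max() < 0.5

    def test_determinism(self, mini_mr_degraded):
        a = extract_control_points(mini_mr_degraded)
        b = extract_control_points(mini_mr_degraded)
        assert np.array_equal(a.coords, b.coords)


class TestAdaptiveVsGlobalThreshold:
    def test_global_threshold_misses_points_in_biased_stack(self, mini_geo, mini_mr):
        """A single absolute threshold tuned on one slice loses points on
        slices deeper in a biased stack; the adaptive pipeline does not."""
        from mrdistcorr import apply_bias_field
        from mrdistcorr.detect import detect_slice

        biased = apply_bias_field(mini_mr, 0.3, seed=3)
        inv = invert_if_mr(biased)
        p_ad = DetectionParams().resolved((1.0, 1.0))
        zc = biased.axis_coords(2)
        sheet_ks = [int(np.argmin(np.abs(zc - zs))) for zs in mini_geo.sheet_positions()]
        # tightest threshold that keeps the grid on the reference slice:
        # just below the grid's inverted intensity there
        ref = np.asarray(inv.data[:, :, sheet_ks[0]], float)
        grid_support = mini_mr.data[:, :, sheet_ks[0]] < 500  # grid is dark in MR
        thr = float(np.percentile(ref[grid_support], 2.0)) - 1.0
        p_fix = DetectionParams(threshold_mode="fixed", fixed_threshold=thr).resolved(
            (1.0, 1.0)
        )
        origin2d = (biased.origin_mm[0], biased.origin_mm[1])
        n_adaptive, n_fixed = [], []
        for k in sheet_ks:
            img = np.asarray(inv.data[:, :, k], float)
            n_adaptive.append(len(detect_slice(img, (1, 1), origin2d, p_ad)[0]))
            n_fixed.append(len(detect_slice(img, (1, 1), origin2d, p_fix)[0]))
        expected = mini_geo.points_per_row**2
        assert all(n == expected for n in n_adaptive)
        assert min(n_fixed) < expected  # the fixed threshold loses points
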