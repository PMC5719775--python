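"""Simulator: geometry, ground-truth field, forward warp, artifacts."""

import numpy as np
import pytest

from mrdistcorr import (
    AcquisitionConfig,
    DistortionModel,
    PhantomGeometry,
    add_noise_and_bubbles,
    apply_bias_field,
    extract_control_points,
    rasterize_phantom,
    true_displacement,
    unsharp_mask,
    warp_volume,
)
from conftest import MINI_NOISE, nearest_errors


class TestGeometry:
    def test_default_matches_physical_phantom(self):
        g = PhantomGeometry()
        assert g.n_sheets == 17
        assert g.points_per_row == 17
        assert g.point_pitch_mm == 15.0
        assert g.sheet_thickness_mm == 7.6
        assert g.gap_mm == 9.0
        assert g.box_inner_mm == (300.0, 300.0, 300.0)
        assert g.n_points == 4913

    def test_lattice_centered_and_spanning(self):
        g = PhantomGeometry()
        lat = g.nominal_lattice()
        assert np.allclose(lat.mean(axis=0), 0.0)
        # 16 pitches of 15 mm span 240 mm along each in-plane axis
        assert lat[:, 0].max() - lat[:, 0].min() == pytest.approx(240.0)
        assert lat[:, 1].max() - lat[:, 1].min() == pytest.approx(240.0)
        assert lat[:, 2].max() - lat[:, 2].min() == pytest.approx(16 * 16.6)

    def test_single_sheet_point_count(self):
        g = PhantomGeometry(n_sheets=1, points_per_row=5, box_inner_mm=(120, 120, 40))
        assert len(g.nominal_lattice()) == 25

    @pytest.mark.parametrize("bad", [dict(n_sheets=0), dict(points_per_row=1),
                                     dict(point_pitch_mm=-1.0)])
    def test_invalid_geometry_rejected(self, bad):
        with pytest.raises(ValueError):
            PhantomGeometry(**bad)


class TestRasterize:
    def test_detected_centroids_on_nominal_lattice(self, mini_geo, mini_nominal,
                                                   mini_mr, mini_ct):
        for vol in (mini_mr, mini_ct):
            cps = extract_control_points(vol)
            assert len(cps) == mini_geo.n_points
            assert nearest_errors(cps.coords, mini_nominal).max() < 0.5

    def test_modality_polarity(self, mini_mr, mini_ct):
        # MR: oil bright, grid dark; CT: grid bright
        center = tuple(s // 2 for s in mini_mr.shape)  # a grid crossing
        oil = (center[0] + 7, center[1] + 7, center[2])
        assert mini_mr.data[oil] > mini_mr.data[center]
        assert mini_ct.data[oil] < mini_ct.data[center]

    def test_phantom_must_fit(self, mini_geo):
        with pytest.raises(ValueError):
            rasterize_phantom(mini_geo, (1.0, 1.0, 1.0), "MR", matrix=(50, 50, 50))


class TestTrueDisplacement:
    def test_zero_model(self):
        m = DistortionModel.zero()
        pts = np.array([[0.0, 0.0, 0.0], [100.0, -50.0, 20.0]])
        assert np.allclose(true_displacement(m, pts), 0.0)

    def test_b0_polarity_sign_symmetry(self):
        m = DistortionModel.pure_b0(1.0)
        pts = np.array([[80.0, 10.0, -60.0], [-40.0, 0.0, 100.0]])
        fwd = true_displacement(m, pts, "forward")
        rev = true_displacement(m, pts, "reverse")
        assert np.allclose(fwd, -rev)
        assert np.allclose(0.5 * (fwd + rev), 0.0)

    def test_cubic_closed_form(self):
        m = DistortionModel(coeffs_x={(3, 0, 0): 1e-6})
        d = true_displacement(m, np.array([[100.0, 0.0, 0.0]]))
        assert d[0, 0] == pytest.approx(1.0)
        assert d[0, 1] == d[0, 2] == 0.0

    def test_default_study_field_envelope(self):
        m = DistortionModel.default_study()
        # negligible at the isocenter, ~5.5 mm maximum over the lattice VOI
        assert np.linalg.norm(m.system_displacement([[0, 0, 0]])) <= 0.1
        assert m.max_over_voi((120.0, 120.0, 132.8)) == pytest.approx(5.5, abs=0.05)


class TestWarp:
    def test_zero_model_is_identity(self, mini_mr):
        out = warp_volume(mini_mr, DistortionModel.zero())
        assert np.abs(out.data - mini_mr.data).max() < 1e-3 * mini_mr.data.max()

    def test_constant_shift_moves_centroids(self, mini_mr, mini_nominal):
        m = DistortionModel(coeffs_x={(0, 0, 0): 5.0})
        out = warp_volume(mini_mr, m)
        cps = extract_control_points(out)
        shifted = mini_nominal + np.array([5.0, 0.0, 0.0])
        err = nearest_errors(cps.coords, shifted)
        assert len(cps) == len(mini_nominal)
        assert err.max() < 0.5

    def test_forward_reverse_b0_antisymmetry(self, mini_mr, mini_nominal):
        m = DistortionModel.pure_b0(1.0)
        m.validity_mm = (75.0, 75.0, 75.0)
        from scipy.spatial import cKDTree

        disp = {}
        for pol in ("forward", "reverse"):
            cfg = AcquisitionConfig(read_polarity=pol, voxel_mm=(1, 1, 1))
            cps = extract_control_points(warp_volume(mini_mr, m, cfg))
            assert len(cps) == len(mini_nominal)
            _, nn = cKDTree(cps.coords).query(mini_nominal)
            disp[pol] = cps.coords[nn] - mini_nominal
        assert np.allclose(disp["forward"][:, 0], -disp["reverse"][:, 0], atol=0.15)
        assert np.abs(0.5 * (disp["forward"] + disp["reverse"])).max() < 0.15


class TestBiasField:
    def test_zero_amplitude_identity(self, mini_mr):
        out = apply_bias_field(mini_mr, 0.0, seed=1)
        assert np.array_equal(out.data, mini_mr.data)

    def test_amplitude_and_mean_preservation(self, mini_mr):
        out = apply_bias_field(mini_mr, 0.3, seed=3)
        ratio = out.data.mean() / mini_mr.data.mean()
        assert abs(ratio - 1.0) < 0.02
        oil = mini_mr.data > 900  # oil voxels only; air/grid medians are degenerate
        med = []
        for k in range(0, mini_mr.shape[2], 5):
            sel = oil[:, :, k]
            if sel.sum() > 500:
                med.append(float(np.median(out.data[:, :, k][sel])) / 1000.0)
        spread = max(med) - min(med)
        assert 0.05 < spread < 0.7  # slices visibly modulated, up to ~30% each way

    def test_unsharp_mask_removes_smooth_bias(self):
        # a pure bias pattern whose scale is much larger than the unsharp
        # sigma is flattened to a few percent of its swing
        x = np.arange(240)[:, None]
        y = np.arange(240)[None, :]
        bias = 1000.0 * (1 + 0.3 * np.sin(2 * np.pi * x / 900 + 0.4)
                         * np.cos(2 * np.pi * y / 900 - 0.2))
        resid = unsharp_mask(bias, 45.0, (1.0, 1.0))
        amplitude = 2 * 0.3 * 1000.0  # peak-to-peak swing of the bias
        interior = resid[50:-50, 50:-50]  # borders belong to air, not grid
        assert np.abs(interior).max() < 0.05 * amplitude


class TestNoiseAndBubbles:
    def test_zero_noise_identity(self, mini_mr):
        out = add_noise_and_bubbles(mini_mr, 0.0, 0, seed=1)
        assert np.array_equal(out.data, mini_mr.data)

    def test_seed_determinism(self, mini_geo, mini_mr):
        a = add_noise_and_bubbles(mini_mr, MINI_NOISE, 5, seed=9, geometry=mini_geo)
        b = add_noise_and_bubbles(mini_mr, MINI_NOISE, 5, seed=9, geometry=mini_geo)
        assert np.array_equal(a.data, b.data)

    def test_bubbles_do_not_change_points(self, mini_geo, mini_mr, mini_mr_points):
        """Off-grid air bubbles must alter neither the point count nor any
        retained centroid, even though a naive threshold sees extra blobs."""
        from scipy.spatial import cKDTree

        out = add_noise_and_bubbles(mini_mr, 0.0, 8, seed=21, geometry=mini_geo)
        cps = extract_control_points(out)
        assert len(cps) == len(mini_mr_points)
        d, _ = cKDTree(mini_mr_points.coords).query(cps.coords)
        assert d.max() < 0.1

    def test_bubbles_fool_naive_single_threshold(self, mini_geo, mini_mr):
        """A plain intensity threshold on an oil-gap slice produces spurious
        dot-sized blobs at bubbles; the crossing detector reports none."""
        from scipy import ndimage

        from mrdistcorr import invert_if_mr, unsharp_mask
        from mrdistcorr.detect import DetectionParams, detect_slice

        out = add_noise_and_bubbles(mini_mr, 0.0, 12, seed=3, geometry=mini_geo)
        inv = invert_if_mr(out)
        # the oil-gap slice most affected by a bubble
        diff = np.abs(out.data.astype(float) - mini_mr.data).sum(axis=(0, 1))
        gap = np.ones(mini_mr.shape[2], bool)
        zc = mini_mr.axis_coords(2)
        for zs in mini_geo.sheet_positions():
            gap &= np.abs(zc - zs) > mini_geo.sheet_thickness_mm / 2 + 1
        k = int(np.argmax(np.where(gap, diff, 0)))
        assert diff[k] > 0, "no bubble landed in an oil gap for this seed"
        img = np.asarray(inv.data[:, :, k], float)
        u = unsharp_mask(img, 45.0, (1.0, 1.0))
        naive = u > 0.5 * np.median(u[u > 0])
        lab, _ = ndimage.label(naive)
        sizes = np.bincount(lab.ravel())[1:]
        n_blobs = int(((sizes >= 3) & (sizes <= 200)).sum())
        df, _ = detect_slice(img, (1.0, 1.0), (inv.origin_mm[0], inv.origin_mm[1]),
                             DetectionParams().resolved((1.0, 1.0)))
        assert n_blobs > len(df)
        assert len(df) == 0
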