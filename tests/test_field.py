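"""Field estimation: B0 averaging, double estimate, iteration, maps, stats."""

import numpy as np
import pandas as pd
import pytest

from mrdistcorr import (
    CorrespondenceSet,
    DisplacementSamples,
    DistortionModel,
    IterationConfig,
    PhantomGeometry,
    average_forward_reverse,
    build_map,
    first_order_estimate,
    iterate_field,
    per_axis_displacement,
    statistics,
)
from mrdistcorr.field import build_orientation_maps
from mrdistcorr.phantom import ideal_orientation_samples


GEO = PhantomGeometry(n_sheets=9, points_per_row=9, box_inner_mm=(180, 180, 180))
LAT_HALF = (60.0, 60.0, 66.4)


def study_model(**kw):
    kw.setdefault("scale", 0.5)
    kw.setdefault("with_b0", False)
    kw.setdefault("half_extents", LAT_HALF)
    return DistortionModel.default_study(**kw)


def orientation_samples(model, **kw):
    return {
        o: ideal_orientation_samples(model, GEO, o, **kw)
        for o in ("transverse", "sagittal", "coronal")
    }


def pairs_from(ct, mr, orientation="transverse"):
    df = pd.DataFrame(
        {
            "x_ct": ct[:, 0], "y_ct": ct[:, 1], "z_ct": ct[:, 2],
            "x_mr": mr[:, 0], "y_mr": mr[:, 1], "z_mr": mr[:, 2],
            "sheet": 0,
        }
    )
    return CorrespondenceSet(df, grid_orientation=orientation)


class TestPerAxisDisplacement:
    def test_identical_points_zero(self):
        ct = np.random.default_rng(0).uniform(-50, 50, (20, 3))
        s = per_axis_displacement(pairs_from(ct, ct))
        assert np.allclose(s.d, 0.0)
        assert np.allclose(s.dr, 0.0)

    def test_three_four_five(self):
        ct = np.zeros((1, 3))
        mr = np.array([[3.0, 4.0, 0.0]])
        s = per_axis_displacement(pairs_from(ct, mr))
        assert s.dr[0] == pytest.approx(5.0)

    def test_total_is_vector_norm_for_every_sample(self):
        rng = np.random.default_rng(3)
        ct = rng.uniform(-100, 100, (200, 3))
        mr = ct + rng.normal(0, 2, (200, 3))
        s = per_axis_displacement(pairs_from(ct, mr))
        assert np.allclose(s.dr, np.sqrt((s.d**2).sum(axis=1)))


class TestAverageForwardReverse:
    def test_identical_sets_unchanged(self, mini_mr_points):
        avg = average_forward_reverse(mini_mr_points, mini_mr_points)
        assert np.allclose(np.sort(avg.coords, 0), np.sort(mini_mr_points.coords, 0))

    def test_coordinate_mean(self):
        from test_register import as_point_set

        fwd = as_point_set([[10.2, 0.0, 0.0]])
        rev = as_point_set([[9.8, 0.0, 0.0]])
        avg = average_forward_reverse(fwd, rev)
        assert avg.coords[0, 0] == pytest.approx(10.0)

    def test_pure_b0_cancels(self):
        from test_register import as_point_set

        model = DistortionModel.pure_b0(1.0)
        nom = GEO.nominal_lattice()
        fwd = as_point_set(nom + model.displacement(nom, "forward"))
        rev = as_point_set(nom + model.displacement(nom, "reverse"))
        avg = average_forward_reverse(fwd, rev)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(nom).query(avg.coords)
        assert d.max() < 1e-9


class TestFirstOrder:
    def test_double_estimate_arithmetic(self):
        # dx = (dx_tra + dx_cor) / 2, per axis, at a common lattice
        nom = GEO.nominal_lattice()
        mk = lambda orient, vec: DisplacementSamples(
            sites=GEO.nominal_lattice(orient),
            d=np.tile(vec, (GEO.n_points, 1)),
            grid_orientation=orient,
        )
        tra = mk("transverse", [1.0, 0.4, 0.0])
        sag = mk("sagittal", [0.0, 0.8, 0.5])
        cor = mk("coronal", [2.0, 0.0, 0.7])
        fo = first_order_estimate(tra, sag, cor)
        assert np.allclose(fo.d[:, 0], 1.5, atol=1e-6)
        assert np.allclose(fo.d[:, 1], 0.6, atol=1e-6)
        assert np.allclose(fo.d[:, 2], 0.6, atol=1e-6)

    def test_zero_fields_zero(self):
        s = orientation_samples(DistortionModel.zero())
        fo = first_order_estimate(s["transverse"], s["sagittal"], s["coronal"])
        assert np.abs(fo.d).max() < 1e-9

    def test_exact_for_separable_field(self):
        # in-plane values independent of the through-plane coordinate:
        # the first-order estimate is already exact
        model = DistortionModel.separable_linear((0.02, 0.015, 0.01))
        s = orientation_samples(model)
        fo = first_order_estimate(s["transverse"], s["sagittal"], s["coronal"])
        truth = model.system_displacement(fo.sites)
        assert np.abs(fo.d - truth).max() < 0.02


class TestIterate:
    def test_constant_field_converges_immediately(self):
        model = DistortionModel(
            coeffs_x={(0, 0, 0): 2.0}, coeffs_y={(0, 0, 0): -1.0},
            coeffs_z={(0, 0, 0): 0.5},
        )
        s = orientation_samples(model)
        out, n, conv, info = iterate_field(s["transverse"], s["sagittal"], s["coronal"])
        assert conv and n == 1
        assert np.allclose(out.d, [2.0, -1.0, 0.5], atol=1e-6)

    def test_cubic_field_iteration_beats_first_order(self):
        # full-size lattice: plenty of interior sites where the first-order
        # through-plane bias is the only error source
        geo = PhantomGeometry()
        model = DistortionModel.default_study(with_b0=False)
        s = {
            o: ideal_orientation_samples(model, geo, o)
            for o in ("transverse", "sagittal", "coronal")
        }
        maps = build_orientation_maps(s["transverse"], s["sagittal"], s["coronal"])
        fo = first_order_estimate(s["transverse"], s["sagittal"], s["coronal"], maps=maps)
        it, n, conv, _ = iterate_field(
            s["transverse"], s["sagittal"], s["coronal"], init=fo, maps=maps
        )
        truth = model.system_displacement(fo.sites)
        e_fo = np.linalg.norm(fo.d - truth, axis=1)
        e_it = np.linalg.norm(it.d - truth, axis=1)
        assert conv
        interior = np.all(np.abs(fo.sites) < 125.0, axis=1)
        biased = interior & (e_fo > 0.1)
        assert biased.sum() > 100
        assert (e_it[biased] < e_fo[biased]).mean() > 0.9
        rms_fo = np.sqrt((e_fo[interior] ** 2).mean())
        rms_it = np.sqrt((e_it[interior] ** 2).mean())
        # iterated error is floored by interpolating the field's harmonic
        # between sheets, so the gain is bounded but must stay decisive
        assert rms_it < 0.7 * rms_fo

    def test_converges_within_four_iterations(self):
        model = study_model()
        s = orientation_samples(model)
        out, n, conv, _ = iterate_field(
            s["transverse"], s["sagittal"], s["coronal"],
            config=IterationConfig(phi_mm=0.2),
        )
        assert conv and n <= 4

    def test_axis_order_robustness(self):
        model = study_model()
        s = orientation_samples(model)
        args = (s["transverse"], s["sagittal"], s["coronal"])
        a, _, _, _ = iterate_field(*args, config=IterationConfig(axis_order=("x", "y", "z")))
        b, _, _, _ = iterate_field(*args, config=IterationConfig(axis_order=("z", "y", "x")))
        diff = np.abs(a.d - b.d)
        scale = np.maximum(np.abs(a.d), 0.5)  # 2% of local magnitude, floored
        assert np.all(diff <= 0.02 * scale)

    def test_parameter_recovery_noiseless(self):
        # any smooth degree-3 field a few mm strong is recovered to well
        # under the iteration cutoff at noiseless detection
        for seed in (0, 1):
            rng = np.random.default_rng(seed)
            model = study_model(scale=float(rng.uniform(0.3, 0.6)))
            s = orientation_samples(model)
            out, _, conv, _ = iterate_field(s["transverse"], s["sagittal"], s["coronal"])
            truth = model.system_displacement(out.sites)
            rms = np.sqrt(((out.d - truth) ** 2).mean())
            assert conv and rms < 0.2


class TestDistortionMap:
    def test_exact_at_sites_and_accurate_off_lattice(self):
        model = study_model()
        model.harmonics = ()  # pure degree-3 field, fully within spline reach
        s = ideal_orientation_samples(model, GEO, "transverse")
        samples = DisplacementSamples(
            sites=s.sites, d=model.system_displacement(s.sites)
        )
        dmap = build_map(samples)
        # exact at sample sites
        got = dmap.evaluate(samples.sites[::17])
        assert np.abs(got - samples.d[::17]).max() < 1e-6
        # accurate between sites, inside the VOI
        rng = np.random.default_rng(7)
        q = rng.uniform(-0.85, 0.85, (300, 3)) * np.array(LAT_HALF)
        truth = model.system_displacement(q)
        assert np.abs(dmap.evaluate(q) - truth).max() < 0.05

    def test_zero_samples_zero_map(self):
        sites = GEO.nominal_lattice()
        dmap = build_map(DisplacementSamples(sites=sites, d=np.zeros_like(sites)))
        q = np.random.default_rng(0).uniform(-60, 60, (50, 3))
        assert np.abs(dmap.evaluate(q)).max() < 1e-9

    def test_scattered_fallback(self, caplog):
        import logging

        rng = np.random.default_rng(5)
        sites = rng.uniform(-50, 50, (300, 3))  # not a lattice
        d = 0.01 * sites
        with caplog.at_level(logging.WARNING, logger="mrdistcorr.field"):
            dmap = build_map(DisplacementSamples(sites=sites, d=d))
        q = rng.uniform(-30, 30, (40, 3))
        assert np.abs(dmap.evaluate(q) - 0.01 * q).max() < 0.05


class TestStatistics:
    def test_single_sample(self):
        s = DisplacementSamples(sites=[[0, 0, 0]], d=[[3.0, 4.0, 0.0]])
        st = statistics(s)
        assert st.table.loc["r", "mean_mm"] == pytest.approx(5.0)
        assert st.table.loc["r", "max_mm"] == pytest.approx(5.0)
        assert st.table.loc["r", "std_mm"] == pytest.approx(0.0)

    def test_all_zero(self):
        sites = GEO.nominal_lattice()
        st = statistics(DisplacementSamples(sites=sites, d=np.zeros_like(sites)))
        assert (st.table.to_numpy() == 0).all()

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        sites = GEO.nominal_lattice()
        d = rng.normal(0, 1.5, sites.shape)
        st = statistics(DisplacementSamples(sites=sites, d=d))
        # independent pass over the list
        for i, ax in enumerate("xyz"):
            v = np.abs(d[:, i])
            assert st.table.loc[ax, "mean_mm"] == pytest.approx(v.mean())
            assert st.table.loc[ax, "std_mm"] == pytest.approx(v.std())
            assert st.table.loc[ax, "max_mm"] == pytest.approx(v.max())
        r = np.linalg.norm(d, axis=1)
        assert st.table.loc["r", "max_mm"] == pytest.approx(r.max())
        # per-plane profile: one entry per sheet, each the plane's max
        prof = st.profile
        assert len(prof) == GEO.n_sheets
        z0 = GEO.sheet_positions()[0]
        sel = np.abs(sites[:, 2] - z0) < 1.0
        assert prof["max_r_mm"].iloc[0] == pytest.approx(r[sel].max())
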