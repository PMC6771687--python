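"""Landmark extraction, transform fitting, overlay precision."""

import numpy as np
import pytest
from skimage import transform as sktf

from locmorph.registration import (
    PointMatch,
    ThinPlateSpline,
    apply_transform,
    fiducial_center_of_mass,
    fiducial_endpoints,
    fit_transform,
    leave_one_out_precision,
    matches_from_dataframe,
    matches_to_dataframe,
    overlay_precision,
)
from locmorph.render import RenderedImage


def _matches(src, dst, kind="center_of_mass"):
    return [
        PointMatch(tuple(d), tuple(s), kind=kind, fiducial_id=i)
        for i, (s, d) in enumerate(zip(src, dst))
    ]


class TestCenterOfMass:
    def test_single_pixel(self):
        g = np.zeros((10, 10))
        g[3, 7] = 5.0
        x, y = fiducial_center_of_mass(RenderedImage(g, 10.0), (0, 10, 0, 10))
        assert (x, y) == (pytest.approx(75.0), pytest.approx(35.0))

    def test_symmetric_blob_geometric_center(self):
        g = np.zeros((11, 11))
        g[4:7, 4:7] = [[1, 2, 1], [2, 8, 2], [1, 2, 1]]
        x, y = fiducial_center_of_mass(RenderedImage(g, 10.0), (0, 11, 0, 11))
        assert x == pytest.approx(55.0) and y == pytest.approx(55.0)

    def test_matches_direct_sum_oracle(self, rng):
        g = rng.random((15, 20))
        img = RenderedImage(g, 10.0, origin=(30.0, 60.0))
        x, y = fiducial_center_of_mass(img, (2, 12, 3, 18))
        w = g[2:12, 3:18]
        rr, cc = np.mgrid[2:12, 3:18]
        ox = 30.0 + ((w * cc).sum() / w.sum() + 0.5) * 10.0
        oy = 60.0 + ((w * rr).sum() / w.sum() + 0.5) * 10.0
        assert x == pytest.approx(ox) and y == pytest.approx(oy)

    def test_zero_intensity_roi_rejected(self):
        with pytest.raises(ValueError):
            fiducial_center_of_mass(RenderedImage(np.zeros((5, 5)), 10.0), (0, 5, 0, 5))


class TestEndpoints:
    def test_horizontal_rod_end_pixels(self):
        m = np.zeros((7, 24), dtype=bool)
        m[3, 2:22] = True
        p1, p2 = fiducial_endpoints(m, 10.0)
        assert p1 == (pytest.approx(25.0), pytest.approx(35.0))
        assert p2 == (pytest.approx(215.0), pytest.approx(35.0))

    def test_rotation_equivariance(self):
        m = np.zeros((24, 7), dtype=bool)
        m[2:22, 3] = True
        p1, p2 = fiducial_endpoints(m, 10.0)
        assert p1 == (pytest.approx(35.0), pytest.approx(25.0))
        assert p2 == (pytest.approx(35.0), pytest.approx(215.0))

    def test_matches_exhaustive_projection_search(self, rng):
        # ragged synthetic rod vs brute-force farthest-projection search
        m = np.zeros((30, 60), dtype=bool)
        m[12:18, 5:55] = True
        m[13:17, 3:57] = True
        ridx = rng.integers(12, 18, 30)
        cidx = rng.integers(5, 55, 30)
        m[ridx, cidx] = True
        p1, p2 = fiducial_endpoints(m, 10.0)
        rr, cc = np.nonzero(m)
        r0, c0 = rr.mean(), cc.mean()
        cov = np.cov(np.stack([cc - c0, rr - r0]))
        ax = np.linalg.eigh(cov)[1][:, -1]
        proj = (cc - c0) * ax[0] + (rr - r0) * ax[1]
        expected = sorted(
            (
                ((c0 + p * ax[0] + 0.5) * 10.0, (r0 + p * ax[1] + 0.5) * 10.0)
                for p in (proj.min(), proj.max())
            )
        )
        assert np.allclose(p1, expected[0]) and np.allclose(p2, expected[1])

    def test_compact_blob_rejected(self):
        m = np.zeros((10, 10), dtype=bool)
        m[3:7, 3:7] = True
        with pytest.raises(ValueError, match="rod"):
            fiducial_endpoints(m, 10.0)

    def test_two_components_rejected(self):
        m = np.zeros((10, 30), dtype=bool)
        m[2, 1:9] = True
        m[7, 15:25] = True
        with pytest.raises(ValueError, match="component"):
            fiducial_endpoints(m, 10.0)


class TestFitTransform:
    def test_identity_matches_zero_residual(self, rng):
        pts = rng.uniform(0, 1000, (6, 2))
        model = fit_transform(_matches(pts, pts), "similarity")
        assert model.rms_residual == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(model.transform(pts), pts, atol=1e-9)

    @pytest.mark.parametrize("n_points", [2, 3, 5, 20])
    def test_similarity_exact_recovery(self, n_points, rng):
        src = rng.uniform(0, 2000, (n_points, 2))
        tf = sktf.SimilarityTransform(
            scale=1.1, rotation=np.deg2rad(30), translation=(50, -20)
        )
        model = fit_transform(_matches(src, tf(src)), "similarity")
        assert model.parameters["scale"] == pytest.approx(1.1, rel=1e-9)
        assert model.parameters["rotation_rad"] == pytest.approx(
            np.deg2rad(30), rel=1e-9
        )
        np.testing.assert_allclose(
            model.parameters["translation"], (50, -20), atol=1e-6
        )
        assert model.rms_residual < 1e-9 * 2000

    def test_affine_collinear_rejected(self):
        src = np.array([[0.0, 0.0], [1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        with pytest.raises(ValueError, match="collinear"):
            fit_transform(_matches(src, src), "affine")

    def test_too_few_matches_rejected(self):
        src = np.array([[0.0, 0.0]])
        with pytest.raises(ValueError, match="similarity"):
            fit_transform(_matches(src, src), "similarity")

    def test_rigid_fit_locks_scale(self, rng):
        src = rng.uniform(0, 1000, (8, 2))
        dst = 1.3 * src + 10.0  # scaled data; rigid must not absorb the scale
        model = fit_transform(_matches(src, dst), "rigid")
        assert model.parameters["scale"] == 1.0
        R = model.parameters["rotation"]
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_tps_interpolates_affine_configuration(self, rng):
        src = rng.uniform(0, 1000, (6, 2))
        A = np.array([[1.2, 0.1], [-0.2, 0.9]])
        dst = src @ A.T + (30.0, -40.0)
        model = fit_transform(_matches(src, dst), "thin_plate_spline")
        np.testing.assert_allclose(model.transform(src), dst, atol=1e-6)
        assert model.parameters["bending_energy"] == pytest.approx(0.0, abs=1e-6)

    def test_tps_high_regularization_approaches_affine(self, rng):
        src = rng.uniform(0, 100, (10, 2))
        dst = src + rng.normal(0, 5, (10, 2))
        affine = fit_transform(_matches(src, dst), "affine")
        probe = rng.uniform(0, 100, (20, 2))
        prev_gap = np.inf
        for reg in (1e4, 1e7, 1e10):
            tps = ThinPlateSpline(src, dst, reg=reg)
            gap = np.abs(tps(probe) - affine.transform(probe)).max()
            assert gap < prev_gap + 1e-12
            prev_gap = gap
        assert prev_gap < 1e-3


class TestApplyTransform:
    def test_identity_model(self, rng):
        pts = rng.uniform(0, 100, (5, 2))
        model = fit_transform(_matches(pts, pts), "similarity")
        np.testing.assert_allclose(apply_transform(pts, model), pts, atol=1e-9)

    def test_forward_then_inverse_points(self, rng):
        src = rng.uniform(0, 1000, (6, 2))
        tf = sktf.SimilarityTransform(scale=0.9, rotation=0.4, translation=(5, 9))
        fwd = fit_transform(_matches(src, tf(src)), "similarity")
        inv = fit_transform(
            [PointMatch(tuple(s), tuple(d)) for s, d in zip(src, tf(src))],
            "similarity",
        )
        round_trip = apply_transform(apply_transform(src, fwd), inv)
        np.testing.assert_allclose(round_trip, src, atol=1e-6)

    def test_integer_translation_matches_rolled_image(self, rng):
        g = rng.random((20, 20))
        img = RenderedImage(g, 10.0)
        src = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0], [70.0, 30.0]])
        dst = src + (30.0, 50.0)  # +3 px in x, +5 px in y
        model = fit_transform(_matches(src, dst), "similarity")
        out = apply_transform(img, model)
        rolled = np.roll(np.roll(g, 5, axis=0), 3, axis=1)
        np.testing.assert_allclose(out.grid[6:, 4:], rolled[6:, 4:], atol=1e-9)


class TestOverlayPrecision:
    def test_perfect_alignment_zero(self, rng):
        pts = rng.uniform(0, 100, (5, 2))
        rep = overlay_precision(_matches(pts, pts))
        assert rep.mean == 0.0 and rep.median == 0.0

    def test_constant_offset(self, rng):
        pts = rng.uniform(0, 100, (8, 2))
        rep = overlay_precision(_matches(pts + (10.0, 0.0), pts))
        assert rep.mean == pytest.approx(10.0)
        assert rep.sd == pytest.approx(0.0, abs=1e-9)
        assert rep.mad == pytest.approx(0.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            overlay_precision([])

    def test_statistics_recomputable_from_distances(self, rng):
        pts = rng.uniform(0, 100, (30, 2))
        jit = pts + rng.normal(0, 5, (30, 2))
        rep = overlay_precision(_matches(pts, jit))
        assert rep.median == pytest.approx(np.median(rep.distances))
        assert rep.mad == pytest.approx(
            np.median(np.abs(rep.distances - np.median(rep.distances)))
        )
        assert rep.histogram()["count"].sum() == rep.n_fiducials

    def test_invariant_under_common_rigid_motion(self, rng):
        ref = rng.uniform(0, 500, (12, 2))
        mov = ref + rng.normal(0, 8, ref.shape)
        tf = sktf.SimilarityTransform(rotation=0.7, translation=(123, -45))
        rep1 = overlay_precision(_matches(mov, ref))
        rep2 = overlay_precision(_matches(tf(mov), tf(ref)))
        np.testing.assert_allclose(
            np.sort(rep1.distances), np.sort(rep2.distances), rtol=1e-9
        )

    def test_leave_one_out_not_below_in_sample(self, rng):
        # LOO residuals exceed in-sample residuals on average
        worse = 0
        for trial in range(100):
            r = np.random.default_rng(trial)
            ref = r.uniform(0, 1000, (8, 2))
            mov = ref + r.normal(0, 10, ref.shape)
            matches = _matches(ref, mov)
            model = fit_transform(matches, "similarity")
            loo = leave_one_out_precision(matches, "similarity")
            if loo.mean >= model.rms_residual * 0.8:
                worse += 1
        assert worse >= 85

    def test_matches_dataframe_round_trip(self, rng):
        pts = rng.uniform(0, 100, (4, 2))
        m = _matches(pts, pts + 3.0, kind="endpoint")
        df = matches_to_dataframe(m)
        back = matches_from_dataframe(df)
        assert [b.p_ref for b in back] == [a.p_ref for a in m]
        assert all(b.kind == "endpoint" for b in back)
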