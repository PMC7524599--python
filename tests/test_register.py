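"""Point matching, transform fitting, warping, chart registration."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import swmpam.metrics as metrics
from swmpam.features import FeaturePointSet
from swmpam.phantom import make_grid_chart, make_vessel_phantom, mems_distortion
from swmpam.register import (GeometricTransform, PointPairs, RegistrationError,
                             add_manual_pairs, apply_to_volume, fit_transform,
                             match_points, register_chart, warp_image)
from swmpam.volume import PAVolume


def pset(points, responses=None):
    points = np.asarray(points, dtype=float)
    if responses is None:
        responses = np.ones(len(points))
    return FeaturePointSet(points, responses)


class TestMatching:
    def test_identical_sets_identity_pairing(self, rng):
        pts = rng.random((20, 2)) * 100
        pairs = match_points(pset(pts), pset(pts), max_dist_px=5)
        assert len(pairs) == 20
        assert np.allclose(pairs.src, pairs.dst)

    def test_uniform_offset_matched(self, rng):
        src = rng.random((15, 2)) * 100
        pairs = match_points(pset(src), pset(src + [2.0, 0.0]), max_dist_px=5)
        assert len(pairs) == 15
        assert np.allclose(pairs.dst - pairs.src, [2.0, 0.0])

    def test_jittered_grid_matches_exhaustive_oracle(self, rng):
        rr, cc = np.meshgrid(np.arange(10, 100, 15.0), np.arange(10, 100, 15.0))
        dst = np.column_stack([rr.ravel(), cc.ravel()])
        src = dst + rng.normal(0, 1.0, dst.shape)
        pairs = match_points(pset(src), pset(dst), max_dist_px=5)
        # independent double-loop mutual-nearest check
        expected = []
        for i in range(len(src)):
            dists = [np.hypot(*(src[i] - d)) for d in dst]
            j = int(np.argmin(dists))
            back = [np.hypot(*(s - dst[j])) for s in src]
            if int(np.argmin(back)) == i and dists[j] <= 5:
                expected.append((tuple(src[i]), tuple(dst[j])))
        got = sorted(zip(map(tuple, pairs.src), map(tuple, pairs.dst)))
        assert got == sorted(expected)

    def test_no_match_within_cutoff_raises(self):
        with pytest.raises(RegistrationError):
            match_points(pset([[0.0, 0.0]]), pset([[50.0, 50.0]]), max_dist_px=5)


class TestManualPairs:
    def test_empty_extra_is_identity(self):
        pairs = PointPairs(np.array([[1.0, 2.0]]), np.array([[1.5, 2.5]]))
        merged = add_manual_pairs(pairs, PointPairs(np.empty((0, 2)), np.empty((0, 2))))
        assert len(merged) == 1

    def test_manual_flag_preserved(self):
        pairs = PointPairs(np.array([[1.0, 2.0]]), np.array([[1.5, 2.5]]))
        extra = PointPairs(np.array([[9.0, 9.0]]), np.array([[9.5, 9.5]]))
        merged = add_manual_pairs(pairs, extra)
        assert len(merged) == 2
        assert merged.origin == ["auto", "manual"]

    def test_duplicate_src_rejected(self):
        pairs = PointPairs(np.array([[1.0, 2.0]]), np.array([[1.5, 2.5]]))
        dup = PointPairs(np.array([[1.0, 2.0]]), np.array([[3.0, 3.0]]))
        with pytest.raises(ValueError):
            add_manual_pairs(pairs, dup)


def affine_points(rng, n=20):
    src = rng.random((n, 2)) * 100
    A = np.array([[1.02, 0.05], [-0.03, 0.98]])
    t = np.array([3.0, -2.0])
    return src, src @ A.T + t


class TestFitTransform:
    def test_projective_recovers_affine_exactly(self, rng):
        src, dst = affine_points(rng)
        t = fit_transform(PointPairs(src, dst), "projective")
        assert t.residual_rms < 1e-6
        assert np.allclose(t(src), dst, atol=1e-6)

    def test_polynomial2_recovers_quadratic_warp(self, rng):
        src = rng.random((30, 2)) * 50
        r, c = src[:, 0], src[:, 1]
        dst = np.column_stack([r + 0.002 * c ** 2, c + 0.001 * r * c])
        t = fit_transform(PointPairs(src, dst), "polynomial2")
        assert t.residual_rms < 1e-6
        assert np.allclose(t(src), dst, atol=1e-6)

    def test_underdetermined_projective_rejected(self):
        pairs = PointPairs(np.array([[0, 0], [1, 0], [0, 1.0]]),
                           np.array([[0, 0], [1, 0], [0, 1.0]]))
        with pytest.raises(ValueError):
            fit_transform(pairs, "projective")

    def test_collinear_points_rejected(self):
        src = np.column_stack([np.arange(12.0), np.arange(12.0)])
        with pytest.raises(ValueError):
            fit_transform(PointPairs(src, src + 1.0), "polynomial2")

    def test_lwm_approximates_smooth_warp(self, rng):
        # local weighted mean averages neighbouring local fits, so it
        # approximates (not interpolates) the controls; it should still track
        # a warp that a global quadratic cannot follow
        rr, cc = np.meshgrid(np.arange(0, 100, 20.0), np.arange(0, 100, 20.0))
        src = np.column_stack([rr.ravel(), cc.ravel()])
        dst = src + np.column_stack([0.001 * src[:, 1] ** 2,
                                     5 * np.sin(src[:, 0] / 40.0)])
        t = fit_transform(PointPairs(src, dst), "lwm")
        assert np.abs(t(src) - dst).max() < 0.2

    def test_serialization_roundtrip(self, rng):
        src, dst = affine_points(rng)
        for family in ("projective", "polynomial2", "polynomial3", "lwm"):
            t = fit_transform(PointPairs(src, dst), family)
            t2 = GeometricTransform.from_dict(t.to_dict())
            probe = rng.random((7, 2)) * 100
            assert np.allclose(t(probe), t2(probe))
            assert np.allclose(t.inverse_points(probe), t2.inverse_points(probe))


class TestWarp:
    def _identity(self, rng):
        src, _ = affine_points(rng)
        return fit_transform(PointPairs(src, src.copy()), "projective")

    def test_identity_transform_keeps_image(self, rng):
        img = rng.random((32, 32))
        assert np.allclose(warp_image(img, self._identity(rng), "bilinear"), img, atol=1e-9)

    def test_translation_roundtrip_up_to_border(self, rng):
        img = rng.random((32, 32))
        src = rng.random((12, 2)) * 30
        fwd = fit_transform(PointPairs(src, src + [0.0, 2.0]), "projective")
        back = fit_transform(PointPairs(src, src - [0.0, 2.0]), "projective")
        round_trip = warp_image(warp_image(img, fwd), back)
        assert np.allclose(round_trip[:, 3:-3], img[:, 3:-3], atol=1e-6)

    def test_nearest_creates_no_new_values(self, rng):
        img = np.round(rng.random((32, 32)) * 10)
        src = rng.random((12, 2)) * 30
        t = fit_transform(PointPairs(src, src + rng.normal(0, 1, src.shape)), "projective")
        out = warp_image(img, t, "nearest")
        assert set(np.unique(out)) <= set(np.unique(img)) | {0.0}


class TestRegisterChart:
    def test_zero_distortion_near_identity(self, grid_chart):
        t, diag = register_chart(grid_chart.pixels, grid_chart)
        assert diag["converged"]
        probe = np.column_stack([np.linspace(20, 180, 9), np.linspace(20, 180, 9)])
        assert np.abs(t(probe) - probe).max() < 0.5

    def test_distorted_chart_recovers_scan_map(self, grid_chart):
        dist = mems_distortion(200, 0.3)
        warped = dist.warp_image(grid_chart.pixels)
        t, diag = register_chart(warped, grid_chart)
        assert diag["nmi_final"] > diag["nmi_initial"]
        rr, cc = np.meshgrid(np.arange(20.0, 180, 5), np.arange(20.0, 180, 5),
                             indexing="ij")
        pts = np.column_stack([rr.ravel(), cc.ravel()])
        true_src = np.column_stack([pts[:, 0], dist.inverse(pts[:, 1])])
        err = np.linalg.norm(t.inverse_points(pts) - true_src, axis=1)
        assert err.mean() < 1.0

    def test_epsilon_failure_raises_with_diagnostics(self, grid_chart):
        dist = mems_distortion(200, 0.3)
        warped = dist.warp_image(grid_chart.pixels)
        with pytest.raises(RegistrationError) as exc:
            register_chart(warped, grid_chart, epsilon=0.999)
        assert "nmi_final" in exc.value.diagnostics

    def test_manual_pairs_do_not_degrade_heldout_residual(self, grid_chart):
        dist = mems_distortion(200, 0.35)
        warped = dist.warp_image(grid_chart.pixels)
        from swmpam.register import extract_chart_corners
        src_pts, _ = extract_chart_corners(warped)
        dst_pts = FeaturePointSet(grid_chart.corner_truth,
                                  np.ones(len(grid_chart.corner_truth)))
        pairs = match_points(src_pts, dst_pts, 10.0)
        # correct manual pairs straight from the ground-truth map
        extra_dst = np.array([[100.0, 5.0], [100.0, 195.0], [50.0, 3.0]])
        extra_src = np.column_stack([extra_dst[:, 0], dist.inverse(extra_dst[:, 1])])
        merged = add_manual_pairs(pairs, PointPairs(extra_src, extra_dst))
        t_auto = fit_transform(pairs, "polynomial3")
        t_full = fit_transform(merged, "polynomial3")
        rr, cc = np.meshgrid(np.arange(10.0, 190, 10), np.arange(10.0, 190, 10),
                             indexing="ij")
        held = np.column_stack([rr.ravel(), cc.ravel()])
        held_src = np.column_stack([held[:, 0], dist.inverse(held[:, 1])])
        res_auto = np.linalg.norm(t_auto(held_src) - held, axis=1).mean()
        res_full = np.linalg.norm(t_full(held_src) - held, axis=1).mean()
        assert res_full <= res_auto + 0.05


class TestApplyToVolume:
    def test_identity_keeps_volume(self, rng):
        vol = PAVolume(rng.random((24, 24, 4)))
        src = rng.random((10, 2)) * 20
        t = fit_transform(PointPairs(src, src.copy()), "projective")
        out = apply_to_volume(vol, t)
        assert np.allclose(out.data, vol.data, atol=1e-9)

    def test_warp_commutes_with_slice_extraction(self, rng):
        vol = PAVolume(rng.random((24, 24, 5)))
        src = rng.random((10, 2)) * 20
        t = fit_transform(PointPairs(src, src + rng.normal(0, 0.5, src.shape)),
                          "projective")
        out = apply_to_volume(vol, t)
        for k in (0, 3):
            assert np.allclose(out.lateral_slice(k),
                               warp_image(vol.lateral_slice(k), t))

    def test_per_slice_nmi_improves_on_distorted_phantom(self):
        n, nt = 100, 12
        truth = make_vessel_phantom(n, seed=4, n_branches=8, n_time=nt,
                                    depth_band=(1, nt - 2))
        dist = mems_distortion(n, 0.3)
        distorted = PAVolume(dist.warp_volume(truth))
        chart = make_grid_chart(n, n, 20, 2)
        t, _ = register_chart(dist.warp_image(chart.pixels), chart, epsilon=0.4)
        restored = apply_to_volume(distorted, t)
        improved = total = 0
        for k in range(nt):
            ts = truth[:, :, k].T
            if (ts > 0).sum() < 50:
                continue
            before = metrics.nmi(distorted.lateral_slice(k), ts, bins=2)
            after = metrics.nmi(restored.lateral_slice(k), ts, bins=2)
            total += 1
            # a slice the distortion left untouched cannot improve further
            improved += after > before or (before > 0.999 and after >= before - 1e-9)
        assert total > 0 and improved / total >= 0.95
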