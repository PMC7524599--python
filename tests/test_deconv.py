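"""Modified delay-and-sum deconvolution and guided filtering."""

import numpy as np
import pytest

from swmpam.deconv import (DeconvRegion, build_weight_matrix, das_deconvolve,
                           deconv_layer, default_region, guided_filter,
                           source_term, wavefront_set, _sensor_distances)
from swmpam.geometry import ScanGeometry
from swmpam.metrics import psnr
from swmpam.phantom import (NoiseModel, make_laser_kernel, make_vessel_phantom,
                            mems_distortion, simulate_acquisition)
from swmpam.volume import PAVolume

from conftest import toy_geometry
from oracles import loop_das, naive_guided_filter


class TestSourceTerm:
    def test_perpendicular_wave_vector_vanishes(self):
        assert source_term(np.array([0.0, 1.0, 2.0]), 1.0, np.pi / 2) == pytest.approx(0.0)

    def test_inverse_distance_scaling(self):
        p = np.array([0.0, 1.0, 2.0])
        assert source_term(p, 2.0, 0.0) == pytest.approx(source_term(p, 1.0, 0.0) / 2)

    def test_linear_ramp_on_axis(self):
        # p(d) = a*d sampled at spacing h around d=1 -> dp/dd = a
        a, h = 3.0, 0.1
        p = a * np.array([1 - h, 1.0, 1 + h])
        assert source_term(p, 1.0, 0.0, spacing=h) == pytest.approx(a)

    def test_invalid_distance_rejected(self):
        with pytest.raises(ValueError):
            source_term(np.array([0.0, 1.0, 2.0]), 0.0, 0.0)


class TestWavefrontSet:
    def test_matches_exhaustive_enumeration(self, geometry16):
        shape = (9, 9, 16)
        g = toy_geometry(9, 16)
        region = DeconvRegion(top_radius_px=2.2, height_mm=0.5)
        d, rho2, x, z, (ox, oy, oz) = _sensor_distances(shape, g)
        dz = g.axial_step_mm
        for center in [(4, 4, 8), (0, 0, 0), (8, 8, 15), (4, 2, 5)]:
            got = {(i, j) for i, j, _ in wavefront_set(center, shape, g, region)}
            # dense sweep over fractional sample indices of each A-line
            expect = set()
            target = d[center]
            for di, dj in region.lateral_offsets():
                ii, jj = center[0] + di, center[1] + dj
                if not (0 <= ii < 9 and 0 <= jj < 9):
                    continue
                ks = np.arange(-0.5, 15.51, 0.005)
                dd = np.sqrt(rho2[ii, jj] + (ks * dz - oz) ** 2)
                if np.min(np.abs(dd - target)) < 2e-4:
                    expect.add((ii, jj))
            if not expect:
                expect = {center[:2]}
            assert got == expect

    def test_reflection_symmetry_on_axis(self):
        n, nt = 11, 16
        g = ScanGeometry(scan_area_mm=(n * 4e-3, n * 6e-3),
                         sensor_center_mm=(n // 2 * 4e-3, n // 2 * 6e-3, -8.8))
        region = DeconvRegion(top_radius_px=2.2, height_mm=0.5)
        pts = wavefront_set((5, 5, 8), (n, n, nt), g, region)
        keys = {(i - 5, j - 5, round(k, 6)) for i, j, k in pts}
        assert keys == {(-di, -dj, k) for di, dj, k in keys}

    def test_degenerates_to_centre(self):
        g = toy_geometry(5, 4)
        region = DeconvRegion(top_radius_px=0.0, height_mm=0.5)
        out = wavefront_set((2, 2, 2), (5, 5, 4), g, region)
        assert [(i, j) for i, j, _ in out] == [(2, 2)]


class TestWeightMatrix:
    def test_uniform_volume_uniform_weights(self, geometry16):
        vol = PAVolume(np.ones((16, 16, 8)))
        region = DeconvRegion(top_radius_px=1.5, height_mm=0.3)
        wm = build_weight_matrix(vol, region, geometry16)
        n_off = len(region.lateral_offsets())
        interior = wm.weights[:, 4:-4, 4:-4, :]
        assert np.allclose(interior, 1.0 / n_off)
        assert np.allclose(wm.weights.sum(axis=0), 1.0)

    def test_bright_voxel_dominates(self, geometry16):
        data = np.full((16, 16, 8), 0.01)
        data[8, 8, 4] = 5.0
        vol = PAVolume(data)
        region = DeconvRegion(top_radius_px=1.5, height_mm=0.3)
        wm = build_weight_matrix(vol, region, geometry16)
        centre_weights = wm.weights[:, 9, 8, 4]  # centre adjacent to the hot voxel
        hot = [oi for oi, (di, dj) in enumerate(wm.offsets) if (di, dj) == (-1, 0)]
        assert centre_weights.argmax() == hot[0]

    def test_weights_equal_normalized_region_means(self, rng, geometry16):
        vol = PAVolume(rng.random((12, 12, 8)))
        g = toy_geometry(12, 8)
        region = DeconvRegion(top_radius_px=1.2, height_mm=0.25)
        wm = build_weight_matrix(vol, region, g)
        half = region.half_height_samples(g)
        amp = np.abs(vol.data)
        i, j, k = 6, 6, 4
        means = []
        for di, dj in wm.offsets:
            lo, hi = max(k - half, 0), min(k + half, 7)
            means.append(amp[i + di, j + dj, lo:hi + 1].mean())
        means = np.array(means)
        assert np.allclose(wm.weights[:, i, j, k], means / means.sum())

    def test_zero_region_gives_uniform(self, geometry16):
        vol = PAVolume(np.zeros((16, 16, 8)))
        region = DeconvRegion(top_radius_px=1.5, height_mm=0.3)
        wm = build_weight_matrix(vol, region, geometry16)
        assert np.allclose(wm.weights[:, 8, 8, 4], 1.0 / len(wm.offsets))


class TestDAS:
    def test_matches_triple_loop_oracle(self, rng):
        g = toy_geometry(12, 16)
        vol = PAVolume(rng.normal(size=(12, 10, 16)))
        region = DeconvRegion(top_radius_px=1.6, height_mm=0.4)
        fast = das_deconvolve(vol, g, region)
        slow = loop_das(vol, g, region)
        assert np.allclose(fast.data, slow, rtol=1e-10, atol=1e-12)

    def test_linearity_with_frozen_weights(self, rng):
        g = toy_geometry(10, 12)
        vol = PAVolume(rng.normal(size=(10, 10, 12)))
        region = DeconvRegion(top_radius_px=1.5, height_mm=0.4)
        wm = build_weight_matrix(vol, region, g)
        base = das_deconvolve(vol, g, region, weights=wm)
        scaled = das_deconvolve(vol.with_data(3.0 * vol.data), g, region, weights=wm)
        assert np.allclose(scaled.data, 3.0 * base.data, rtol=1e-10)

    def _acquire(self, truth, n):
        g = toy_geometry(n, truth.shape[2])
        kernel = make_laser_kernel(12.5, g.step_fast_um, g.step_slow_um)
        acq = simulate_acquisition(truth, kernel, mems_distortion(n, 0.0),
                                   NoiseModel(seed=0), g)
        return acq, g

    def test_single_source_localized(self):
        n, nt = 48, 48
        truth = np.zeros((n, n, nt))
        truth[24, 24, 24] = 1.0
        acq, g = self._acquire(truth, n)
        out = das_deconvolve(acq, g, default_region(g))
        assert np.unravel_index(np.argmax(out.data), out.data.shape) == (24, 24, 24)

    def test_two_resolved_sources_localized(self):
        n, nt = 48, 48
        truth = np.zeros((n, n, nt))
        truth[18, 24, 24] = 1.0
        truth[30, 24, 24] = 1.0
        acq, g = self._acquire(truth, n)
        out = das_deconvolve(acq, g, default_region(g))
        flat = np.argsort(out.data.ravel())[::-1]
        top2 = {tuple(np.unravel_index(i, out.data.shape)) for i in flat[:2]}
        assert top2 == {(18, 24, 24), (30, 24, 24)}

    def test_strong_source_enhanced_over_weak_in_shared_region(self):
        n, nt = 48, 48
        truth = np.zeros((n, n, nt))
        truth[24, 24, 18] = 1.0
        truth[26, 24, 30] = 0.5
        acq, g = self._acquire(truth, n)
        out = das_deconvolve(acq, g, default_region(g))

        def peak(vol, p, r=2):
            return np.abs(vol[p[0] - r:p[0] + r + 1, p[1] - r:p[1] + r + 1,
                              p[2] - r:p[2] + r + 1]).max()

        ratio_in = peak(acq.data, (24, 24, 18)) / peak(acq.data, (26, 24, 30))
        ratio_out = peak(out.data, (24, 24, 18)) / peak(out.data, (26, 24, 30))
        assert ratio_out > ratio_in


class TestGuidedFilter:
    def test_identity_limit(self, rng):
        img = rng.random((24, 24))
        out = guided_filter(img, img, radius=1, eps_reg=1e-12)
        assert np.abs(out - img).max() < 1e-6

    def test_constant_guide_is_box_filter(self, rng):
        img = rng.random((16, 16))
        out = guided_filter(img, np.ones((16, 16)), radius=1, eps_reg=1e-3)
        expected = naive_guided_filter(img, np.ones((16, 16)), 1, 1e-3)
        assert np.allclose(out, expected, atol=1e-12)

    def test_matches_naive_reference(self, rng):
        img = rng.random((16, 16))
        guide = rng.random((16, 16))
        ours = guided_filter(img, guide, radius=2, eps_reg=1e-2)
        theirs = naive_guided_filter(img, guide, 2, 1e-2)
        assert np.allclose(ours, theirs, atol=1e-10)

    def test_parameter_validation(self, rng):
        img = rng.random((8, 8))
        with pytest.raises(ValueError):
            guided_filter(img, img[:4], 1, 1e-3)
        with pytest.raises(ValueError):
            guided_filter(img, img, 0, 1e-3)
        with pytest.raises(ValueError):
            guided_filter(img, img, 1, 0.0)


class TestDeconvLayer:
    def test_psnr_improves_on_blurred_phantom(self):
        n, nt = 64, 32
        truth = make_vessel_phantom(n, seed=2, n_branches=4, n_time=nt,
                                    depth_band=(10, 26))
        g = toy_geometry(n, nt)
        kernel = make_laser_kernel(12.5, g.step_fast_um, g.step_slow_um)
        acq = simulate_acquisition(truth, kernel, mems_distortion(n, 0.0),
                                   NoiseModel(seed=1), g)
        out = deconv_layer(acq, g, default_region(g))

        def norm(a):
            a = np.abs(a)
            return a / a.max()

        before = psnr(norm(acq.data), norm(truth))
        after = psnr(norm(out.data), norm(truth))
        assert after > before
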