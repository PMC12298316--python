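import numpy as np
import pytest

from curvislice.enface import EnFaceImage
from curvislice.pattern import (
    PatternSignal,
    fit_gaussian_clip,
    maxpool_reduce,
    pattern_signal,
    rank_ratio,
    region_fft,
    select_candidate,
    thickness,
)
from curvislice.phantom import (
    LayerSpec,
    NoiseSpec,
    PatternSpec,
    PhantomSpec,
    make_phantom,
    true_surface,
)
from curvislice.surface import AffineXY, PolySurface
from curvislice.volume import VoxelScale


class TestRegionFFT:
    def test_constant_region_concentrates_at_dc(self):
        img = EnFaceImage(np.full((32, 32), 3.0))
        spec = region_fft(img, 16, window=False)
        dc = spec[8, 8]
        assert dc == pytest.approx(3.0 * 16 * 16)
        spec[8, 8] = 0.0
        assert np.abs(spec).max() < 1e-9

    def test_cosine_gives_two_symmetric_sidebands(self):
        x = np.arange(64)[:, None]
        img = EnFaceImage(np.ones((64, 64)) + 0.5 * np.cos(2 * np.pi * 5 * x / 64))
        spec = region_fft(img, 64, window=False)
        spec[32, 32] = 0.0
        peaks = np.argwhere(spec > spec.max() * 0.5)
        assert sorted(map(tuple, peaks)) == [(27, 32), (37, 32)]

    def test_parseval_identity(self):
        rng = np.random.default_rng(0)
        img = EnFaceImage(rng.random((40, 40)))
        spec = region_fft(img, 32, window=False)
        region = img.data[4:36, 4:36]
        lhs = np.sum(spec**2) / spec.size
        rhs = np.sum(region**2)
        assert lhs == pytest.approx(rhs, rel=1e-6)

    def test_masked_pixels_contribute_zero_with_warning(self):
        data = np.ones((16, 16))
        mask = np.ones((16, 16), dtype=bool)
        mask[8, 8] = False
        img = EnFaceImage(data, valid_mask=mask)
        with pytest.warns(UserWarning, match="masked"):
            spec = region_fft(img, 16, window=False)
        assert spec[8, 8] == pytest.approx(255.0)  # DC of 255 ones

    def test_oversized_region_rejected(self):
        with pytest.raises(ValueError):
            region_fft(EnFaceImage(np.ones((8, 8))), 16)


class TestMaxpool:
    def test_kernel_one_is_identity(self):
        rng = np.random.default_rng(1)
        a = rng.random((6, 7))
        pooled, coords = maxpool_reduce(a, 1)
        np.testing.assert_array_equal(pooled, a)

    def test_single_hot_value_survives(self):
        a = np.zeros((4, 4))
        a[1, 2] = 7.0
        pooled, coords = maxpool_reduce(a, 2)
        assert pooled.shape == (2, 2)
        assert (pooled == 7.0).sum() == 1
        assert tuple(coords[0, 1]) == (1, 2)

    def test_matches_block_max_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.random((16, 16))
        pooled, coords = maxpool_reduce(a, 4)
        for i in range(4):
            for j in range(4):
                block = a[4 * i : 4 * i + 4, 4 * j : 4 * j + 4]
                assert pooled[i, j] == block.max()
                r, c = coords[i, j]
                assert a[r, c] == pooled[i, j]

    def test_partial_edge_cells(self):
        a = np.arange(25.0).reshape(5, 5)
        pooled, _ = maxpool_reduce(a, 2)
        assert pooled.shape == (3, 3)
        assert pooled[2, 2] == 24.0


class TestRankRatio:
    def test_simple_ranks(self):
        vals = np.concatenate([[10.0, 8.0], np.ones(120)])
        assert rank_ratio(vals.reshape(-1, 1), 2, 100) == pytest.approx(8.0)

    def test_constant_array_unit_ratio(self):
        assert rank_ratio(np.full((12, 12), 3.0), 2, 100) == 1.0

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.random((20, 20))
        flat = np.sort(a.ravel())[::-1]
        for i, j in [(1, 5), (2, 100), (3, 300)]:
            assert rank_ratio(a, i, j) == pytest.approx(flat[i - 1] / flat[j - 1])

    def test_zero_denominator_rejected(self):
        a = np.zeros((11, 11))
        a[0, 0] = 5.0
        with pytest.raises(ZeroDivisionError):
            rank_ratio(a, 1, 100)


def patterned_phantom(offset, seed=0, amplitude=6.0):
    """Single boundary + sinusoidal band centered `offset` voxels above it."""
    return PhantomSpec(
        dims=(144, 144, 128),
        layers=[LayerSpec({"0,0": 70.0, "1,0": 5.0, "2,0": -4.0, "0,2": 3.0}, 80.0, 3.0)],
        pattern=PatternSpec(
            0.25, 0.0, amplitude, layer=0, band=(offset - 2, offset + 2), profile="gauss"
        ),
        noise=NoiseSpec(background=1.0, shape=8.0, readout=0.3, structure_shape=8.0),
        seed=seed,
    )


class TestCandidate:
    def test_candidate_slice_finds_patterned_offset(self):
        spec = patterned_phantom(offset=-8.0, seed=5)
        vol, truth = make_phantom(spec)
        s = true_surface(spec.layers[0], spec.dims)
        sel = select_candidate(vol, s, range(-20, 20), center_size=128, kernel=8)
        assert abs(sel.dz_m - (-8)) <= 1
        assert sel.sharp
        assert sel.n_dominant == 23

    def test_pattern_free_phantom_is_flagged(self):
        spec = PhantomSpec(
            dims=(144, 144, 128),
            layers=[LayerSpec({"0,0": 70.0}, 0.0, 1.0)],
            noise=NoiseSpec(background=1.0, shape=4.0, readout=0.3),
            seed=6,
        )
        vol, _ = make_phantom(spec)
        s = true_surface(spec.layers[0], spec.dims)
        sel = select_candidate(vol, s, range(-10, 10), center_size=128, kernel=8)
        assert not sel.sharp
        assert sel.ratio_per_dz.max() / sel.ratio_per_dz.min() < 2.0

    def test_signal_is_sideband_minus_noise_and_positive_at_candidate(self):
        spec = patterned_phantom(offset=-8.0, seed=7)
        vol, _ = make_phantom(spec)
        s = true_surface(spec.layers[0], spec.dims)
        sel = select_candidate(vol, s, range(-20, 20), center_size=128, kernel=8)
        sig = pattern_signal(vol, s, sel, center_size=128, kernel=8)
        np.testing.assert_array_equal(sig.signal, sig.sideband - sig.noise)
        at_candidate = sig.signal[np.flatnonzero(sig.dz_grid == sel.dz_m)[0]]
        assert at_candidate > 0
        # far from the band the signal sits at the noise level
        far = sig.signal[np.abs(sig.dz_grid - sel.dz_m) > 10]
        assert np.abs(far).max() < 0.05 * at_candidate


class TestGaussianFit:
    def test_exact_gaussian_recovered(self):
        x = np.arange(-20.0, 20.0)
        y = 10.0 * np.exp(-((x + 4.0) ** 2) / (2 * 1.8**2))
        sig = PatternSignal(x, y, np.zeros_like(y))
        initial, clipped, final, l_z = fit_gaussian_clip(sig)
        assert final.amplitude == pytest.approx(10.0, abs=1e-6)
        assert final.center == pytest.approx(-4.0, abs=1e-6)
        assert final.sigma == pytest.approx(1.8, abs=1e-6)
        assert l_z == pytest.approx(3.6, abs=1e-6)

    def test_clipping_does_not_change_exact_gaussian_fit(self):
        x = np.arange(-20.0, 20.0)
        y = 5.0 * np.exp(-((x - 1.0) ** 2) / (2 * 3.0**2))
        sig = PatternSignal(x, y, np.zeros_like(y))
        initial, clipped, final, _ = fit_gaussian_clip(sig)
        assert clipped.dz_grid.size < x.size  # right side was clipped
        assert final.center == pytest.approx(initial.center, abs=1e-6)
        assert final.sigma == pytest.approx(initial.sigma, abs=1e-6)

    def test_noisy_gaussian_parameter_recovery(self):
        rng = np.random.default_rng(8)
        x = np.arange(-20.0, 20.0)
        a, mu, sigma = 100.0, -4.0, 2.5
        y = a * np.exp(-((x - mu) ** 2) / (2 * sigma**2)) + rng.uniform(-5, 5, x.size)
        _, _, final, _ = fit_gaussian_clip(PatternSignal(x, y, np.zeros_like(y)))
        assert final.center == pytest.approx(mu, abs=0.2)
        assert final.sigma == pytest.approx(sigma, rel=0.1)

    def test_width_mode_full_doubles_layer_count(self):
        x = np.arange(-20.0, 20.0)
        y = 10.0 * np.exp(-(x**2) / (2 * 2.0**2))
        sig = PatternSignal(x, y, np.zeros_like(y))
        *_, lz_half = fit_gaussian_clip(sig, width_mode="half")
        *_, lz_full = fit_gaussian_clip(sig, width_mode="full")
        assert lz_full == pytest.approx(2 * lz_half)

    def test_too_few_positive_samples_rejected(self):
        x = np.arange(-5.0, 5.0)
        y = np.full_like(x, -1.0)
        y[3] = 2.0
        with pytest.raises(ValueError):
            fit_gaussian_clip(PatternSignal(x, y, np.zeros_like(y)))


class TestThickness:
    SCALE = VoxelScale(1.0, 1.0, 1.0)

    def test_flat_surface_no_tilt_correction(self):
        s = PolySurface(0, [50.0])
        res = thickness(2.0, s, 0.0, 0.0, self.SCALE, n_medium=1.0)
        assert res.unit_projection == 1.0
        assert res.thickness_um == pytest.approx(2.0)

    def test_three_four_five_projection(self):
        # Mz/Mx * df/dx = 3/4 -> |r| = 5/4 -> projection 0.8
        s = PolySurface(1, [0.0, 0.0, 0.75])  # f = 0.75 x, identity transform
        res = thickness(2.0, s, 0.0, 0.0, self.SCALE, n_medium=1.0)
        assert res.unit_projection == pytest.approx(0.8)
        assert res.thickness_um == pytest.approx(1.6)

    def test_projection_matches_vector_norm_oracle(self):
        rng = np.random.default_rng(9)
        scale = VoxelScale(4.8828, 19.5312, 4.2068)
        s = PolySurface(3, rng.normal(0, 3, 10), transform=AffineXY(80, 80, 60, 60))
        from curvislice.surface import surface_gradient

        gx, gy = surface_gradient(s, 33.0, 41.0)
        r = np.array([scale.mz / scale.mx * gx, scale.mz / scale.my * gy, 1.0])
        res = thickness(3.0, s, 33.0, 41.0, scale, n_medium=1.557)
        assert res.unit_projection == pytest.approx(
            np.dot([0, 0, 1], r / np.linalg.norm(r)), abs=1e-10
        )
        assert 0 < res.unit_projection <= 1
        assert res.thickness_um <= 1.557 * scale.mz * 3.0 + 1e-12

    def test_invalid_inputs_rejected(self):
        s = PolySurface(0, [0.0])
        with pytest.raises(ValueError):
            thickness(0.0, s, 0, 0, self.SCALE)
        with pytest.raises(ValueError):
            thickness(1.0, s, 0, 0, self.SCALE, n_medium=0.9)
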