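import numpy as np
import pytest
from scipy import ndimage as ndi

import mammotex as mx
from mammotex.texture import (DIRECTIONS, FEATURE_NAMES, QuantizedRegion,
                              compute_feature_maps, fractal_dimension,
                              glcm_features, glcm_matrix, histogram_features,
                              quantize, region_directions, round_direction,
                              run_lengths, runlength_features, runlength_stats)


def brute_glcm(q: QuantizedRegion, offsets):
    """Pair enumeration oracle for the symmetric normalized GLCM."""
    G = q.G
    M = np.zeros((G, G))
    H, W = q.mask.shape
    for r in range(H):
        for c in range(W):
            if not q.mask[r, c]:
                continue
            for dr, dc in offsets:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < H and 0 <= c2 < W and q.mask[r2, c2]:
                    i, j = q.levels[r, c] - 1, q.levels[r2, c2] - 1
                    M[i, j] += 1
                    M[j, i] += 1
    s = M.sum()
    return M / s if s else M


def brute_runs(q: QuantizedRegion, direction):
    """Run enumeration oracle: walk every maximal in-mask segment."""
    dr, dc = direction
    H, W = q.mask.shape
    runs = []
    for r in range(H):
        for c in range(W):
            if not q.mask[r, c]:
                continue
            pr, pc = r - dr, c - dc
            if 0 <= pr < H and 0 <= pc < W and q.mask[pr, pc]:
                continue  # not a segment start
            seq = []
            rr, cc = r, c
            while 0 <= rr < H and 0 <= cc < W and q.mask[rr, cc]:
                seq.append(q.levels[rr, cc])
                rr, cc = rr + dr, cc + dc
            k = 0
            while k < len(seq):
                j = k
                while j < len(seq) and seq[j] == seq[k]:
                    j += 1
                runs.append((seq[k], j - k))
                k = j
    lv = np.array([g for g, _ in runs], float)
    ln = np.array([l for _, l in runs], float)
    return lv, ln


def random_region(rng, size=8, G=8):
    levels = rng.integers(1, G + 1, size=(size, size)).astype(np.int32)
    mask = rng.random((size, size)) < 0.7
    if not mask.any():
        mask[0, 0] = True
    return QuantizedRegion(levels=levels, mask=mask, G=G)


class TestQuantize:
    def test_levels_span_1_to_g(self):
        v = np.linspace(0, 1, 1000)
        q = quantize(v, 0.0, 1.0, 16)
        assert q.min() == 1 and q.max() == 16
        assert np.all(np.diff(q) >= 0)

    def test_constant_range_collapses_to_one(self):
        assert np.all(quantize(np.full(5, 3.0), 3.0, 3.0, 8) == 1)

    def test_out_of_range_clipped(self):
        q = quantize(np.array([-1.0, 2.0]), 0.0, 1.0, 4)
        assert list(q) == [1, 4]


class TestHistogramFeatures:
    def test_matches_numpy_oracles(self):
        rng = np.random.default_rng(2)
        v = rng.gamma(3.0, 10.0, size=400)
        f = histogram_features(v, G=32)
        assert f[0] == pytest.approx(np.percentile(v, 5))
        assert f[2] == pytest.approx(np.percentile(v, 95))
        assert f[6] == v.max() and f[8] == v.min()
        assert f[7] == pytest.approx(v.mean())
        assert f[9] == pytest.approx(v.std())
        assert f[11] == pytest.approx(v.sum())
        assert f[12] == pytest.approx(np.median(v))
        from scipy import stats
        assert f[5] == pytest.approx(stats.kurtosis(v))
        assert f[10] == pytest.approx(stats.skew(v))

    def test_constant_region_conventions(self):
        f = histogram_features(np.full(50, 7.0), G=8)
        assert f[4] == 0.0       # entropy
        assert f[5] == 0.0 and f[10] == 0.0 and f[9] == 0.0


class TestGLCM:
    def test_alternating_strip_contrast_one(self):
        # levels 1,2,1,2,... horizontally: every horizontal pair differs by 1
        levels = np.tile(np.array([[1, 2, 1, 2, 1, 2]]), (1, 1)).astype(np.int32)
        q = QuantizedRegion(levels=levels, mask=np.ones_like(levels, bool), G=2)
        f = glcm_features(q, [(0, 1)])
        assert f[0] == pytest.approx(1.0)   # contrast
        assert f[1] == pytest.approx(-1.0)  # perfect anticorrelation

    def test_constant_region_conventions(self):
        q = QuantizedRegion(levels=np.full((5, 5), 3, np.int32),
                            mask=np.ones((5, 5), bool), G=8)
        f = glcm_features(q, [(0, 1), (1, 0)])
        contrast, corr, homog, energy, entropy, idm, shade = f
        assert contrast == 0.0 and energy == 1.0 and entropy == 0.0
        assert homog == 1.0 and idm == 1.0 and corr == 0.0 and shade == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_brute_force_pair_oracle(self, seed):
        rng = np.random.default_rng(seed)
        q = random_region(rng)
        offsets = [DIRECTIONS[rng.integers(4)], DIRECTIONS[rng.integers(4)]]
        np.testing.assert_allclose(glcm_matrix(q, offsets),
                                   brute_glcm(q, offsets), atol=1e-10)

    def test_against_skimage_on_full_rectangle(self):
        from skimage.feature import graycomatrix
        rng = np.random.default_rng(9)
        levels = rng.integers(1, 9, size=(12, 10)).astype(np.int32)
        q = QuantizedRegion(levels=levels, mask=np.ones_like(levels, bool), G=8)
        ours = glcm_matrix(q, [(0, 1)])
        ref = graycomatrix(levels - 1, distances=[1], angles=[0], levels=8,
                           symmetric=True, normed=True)[:, :, 0, 0]
        np.testing.assert_allclose(ours, ref, atol=1e-10)


class TestRunLength:
    def test_single_run_closed_forms(self):
        for N in (3, 7, 12):
            q = QuantizedRegion(levels=np.full((1, N), 4, np.int32),
                                mask=np.ones((1, N), bool), G=8)
            f = runlength_features(q, (0, 1))
            sre, lre = f[0], f[1]
            rp = f[4]
            assert lre == pytest.approx(N**2)
            assert rp == pytest.approx(1.0 / N)
            assert sre == pytest.approx(1.0 / N**2)

    def test_empty_run_list(self):
        assert np.all(runlength_stats(np.array([]), np.array([]), 10, 8) == 0)

    @pytest.mark.parametrize("seed", range(6))
    def test_brute_force_run_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        q = random_region(rng, G=4)
        d = DIRECTIONS[rng.integers(4)]
        lv, ln = run_lengths(q, d)
        blv, bln = brute_runs(q, d)
        # compare as multisets of (level, length)
        ours = sorted(zip(lv, ln))
        ref = sorted(zip(blv, bln))
        assert ours == ref
        np.testing.assert_allclose(
            runlength_features(q, d),
            runlength_stats(blv, bln, q.pixel_count, q.G), atol=1e-10)

    def test_run_count_conserves_pixels(self):
        rng = np.random.default_rng(5)
        q = random_region(rng)
        for d in DIRECTIONS:
            lv, ln = run_lengths(q, d)
            assert ln.sum() == q.pixel_count


class TestStructural:
    def test_fractal_dimension_of_filled_square(self):
        # a filled plane has box-counting dimension 2
        assert fractal_dimension(np.ones((64, 64), bool)) == pytest.approx(2.0, abs=0.05)

    def test_fractal_dimension_of_line(self):
        pat = np.zeros((64, 64), bool)
        pat[32, :] = True
        assert fractal_dimension(pat) == pytest.approx(1.0, abs=0.15)

    def test_small_bbox_flagged_zero(self):
        assert fractal_dimension(np.ones((4, 4), bool)) == 0.0


class TestDirections:
    def test_round_direction_canonical(self):
        assert round_direction((0.0, 1.0)) == (0, 1)
        assert round_direction((0.0, -1.0)) == (0, 1)     # canonical sign
        assert round_direction((1.0, 0.0)) == (1, 0)
        assert round_direction((0.7, 0.7)) == (1, 1)
        assert round_direction((0.7, -0.7)) == (1, -1)

    def test_radial_tangential_orthogonal_for_cardinal_azimuths(self):
        rad, tan = region_directions(np.array([0.0, 90.0, 180.0, -90.0]))
        for r, t in zip(rad, tan):
            dr, dt = DIRECTIONS[r], DIRECTIONS[t]
            assert dr[0] * dt[0] + dr[1] * dt[1] == 0


@pytest.fixture(scope="module")
def computed(anatomy, grid):
    img, truth, an = anatomy
    cfg = mx.RunConfig(gray_levels=32)
    maps = compute_feature_maps(an.standardized_image, grid, cfg)
    return an, grid, maps, cfg


class TestVectorizedAgainstReference:
    """The per-image vectorized extraction must agree with the single-region
    reference implementations on every retained region of a real grid."""

    def test_structural_count_and_shape(self, computed):
        an, grid, maps, cfg = computed
        assert maps.values.shape == (grid.n_regions, 34)
        assert np.all(np.isfinite(maps.values))

    def test_all_regions_match_reference(self, computed):
        an, grid, maps, cfg = computed
        values = an.standardized_image.pixels
        sel = grid.label_map >= 0
        G = cfg.gray_levels
        levels = quantize(values, values[sel].min(), values[sel].max(), G)
        rad, tan = region_directions(grid.azimuth_deg)
        slices = ndi.find_objects(grid.label_map + 1)
        for k in range(grid.n_regions):
            sl = slices[k]
            msk = grid.label_map[sl] == k
            q = QuantizedRegion(levels=levels[sl], mask=msk, G=G)
            ref_hist = histogram_features(values[sl][msk], levels=levels[sl][msk], G=G)
            np.testing.assert_allclose(maps.values[k, :13], ref_hist,
                                       rtol=1e-9, atol=1e-9, err_msg=f"hist region {k}")
            offsets = list({DIRECTIONS[rad[k]], DIRECTIONS[tan[k]]})
            ref_glcm = glcm_features(q, offsets)
            np.testing.assert_allclose(maps.values[k, 13:20], ref_glcm,
                                       rtol=1e-9, atol=1e-9, err_msg=f"glcm region {k}")
            ref_rl = runlength_features(q, DIRECTIONS[rad[k]])
            np.testing.assert_allclose(maps.values[k, 20:31], ref_rl,
                                       rtol=1e-9, atol=1e-9, err_msg=f"rl region {k}")

    def test_structural_full_image_oracle(self, computed):
        from skimage.feature import local_binary_pattern
        an, grid, maps, cfg = computed
        values = an.standardized_image.pixels
        sel = grid.label_map >= 0
        G = cfg.gray_levels
        levels = quantize(values, values[sel].min(), values[sel].max(), G)
        grad = np.hypot(ndi.sobel(values, axis=1), ndi.sobel(values, axis=0))
        codes = local_binary_pattern(levels.astype(np.int32), P=8, R=1, method="uniform")
        for k in (0, grid.n_regions // 2, grid.n_regions - 1):
            m = grid.label_map == k
            assert maps.values[k, 31] == pytest.approx(grad[m].mean() / values[m].mean())
            assert maps.values[k, 33] == pytest.approx((codes[m] != 9).mean())

    def test_intensity_shift_leaves_glcm_runs_invariant(self, anatomy, grid):
        # adding a constant shifts the quantization range with it, so the
        # quantized pattern and all GLCM/run-length features are unchanged
        img, truth, an = anatomy
        cfg = mx.RunConfig(gray_levels=32)
        base = compute_feature_maps(an.standardized_image, grid, cfg)
        from mammotex.io_formats import MammogramImage
        shifted = MammogramImage(pixels=an.standardized_image.pixels + 500.0,
                                 pixel_spacing_mm=an.standardized_image.pixel_spacing_mm)
        other = compute_feature_maps(shifted, grid, cfg)
        np.testing.assert_allclose(other.values[:, 13:31], base.values[:, 13:31],
                                   rtol=1e-9, atol=1e-9)

    def test_axis_aligned_mode_differs(self, computed):
        an, grid, maps, cfg = computed
        ax = compute_feature_maps(an.standardized_image, grid, cfg,
                                  orientation_mode="axis_aligned")
        assert ax.orientation_mode == "axis_aligned"
        # same histogram features, generally different oriented features
        np.testing.assert_allclose(ax.values[:, :13], maps.values[:, :13])
        assert not np.allclose(ax.values[:, 20:31], maps.values[:, 20:31])
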