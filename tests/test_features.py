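"""The five VIA predictors: worked examples and the brute-force GLCM oracle."""

import math

import numpy as np
import pytest
from skimage.color import rgb2hsv

from cervia import features
from cervia.features import (
    FEATURE_NAMES,
    GLCM_OFFSETS,
    astar_mean,
    channel_sd,
    d_ave,
    extract_features,
    features_table,
    glcm_correlation,
    glcm_matrix,
    haralick_correlation,
    quantize,
    ratio_histogram,
    ratio_mode_difference,
)
from conftest import constant_image, make_slice


def block_mask(shape=(64, 64), size=10):
    m = np.zeros(shape, bool)
    m[4 : 4 + size, 4 : 4 + size] = True
    return m


# ---------------------------------------------------------------------------
# ratio-histogram mode differences


class TestRatioModeDifference:
    def test_identical_slices_give_zero(self):
        img = constant_image((64, 64), (100, 80, 60))
        slc = make_slice(img, img.copy(), block_mask())
        assert ratio_mode_difference(slc, "G_over_R") == 0.0
        assert d_ave(slc) == 0.0

    def test_hand_computed_bin_shift(self):
        # G/R: 0.8 -> bin floor(0.8/(2/256)) = 102; 1.2 -> bin 153; shift 51
        pre = constant_image((64, 64), (100, 80, 60))
        post = constant_image((64, 64), (100, 120, 60))
        slc = make_slice(pre, post, block_mask())
        assert ratio_mode_difference(slc, "G_over_R") == 51.0
        assert ratio_mode_difference(slc, "B_over_R") == 0.0
        assert d_ave(slc) == pytest.approx(25.5)  # (51 + 0) / 2

    def test_exact_illumination_invariance(self):
        pre = constant_image((64, 64), (100, 80, 60))
        post = constant_image((64, 64), (100, 120, 60))
        slc = make_slice(pre, post, block_mask())
        half = make_slice(pre // 2, post // 2, block_mask())
        assert d_ave(half) == d_ave(slc)

    def test_approximate_illumination_invariance_on_scene(self, demo_pair_slices):
        """Dimming both images by a constant moves d_ave by at most one bin."""
        _, slices = demo_pair_slices
        for s in slices:
            scaled = make_slice(
                np.clip(np.rint(s.pre * 0.75), 0, 255).astype(np.uint8),
                np.clip(np.rint(s.post * 0.75), 0, 255).astype(np.uint8),
                s.mask,
            )
            assert abs(d_ave(scaled) - d_ave(s)) <= 1.0

    def test_too_few_pixels_is_missing(self):
        img = constant_image((64, 64), (100, 80, 60))
        slc = make_slice(img, img.copy(), block_mask(size=7))  # 49 < 50
        assert math.isnan(ratio_mode_difference(slc, "G_over_R"))

    def test_histogram_conserves_pixels_and_clips_top_bin(self):
        img = constant_image((64, 64), (10, 250, 60))  # ratio 25 -> top bin
        h = ratio_histogram(img, block_mask(), "G_over_R")
        assert h.counts.sum() == 100
        assert h.mode_index == 255

    def test_mode_tie_breaks_to_lowest_bin(self):
        img = constant_image((64, 64), (100, 80, 60))
        img[4:9, 4:14, 1] = 120  # half the mask at ratio 1.2, half at 0.8
        h = ratio_histogram(img, block_mask(), "G_over_R")
        assert h.counts.max() == 50
        assert h.mode_index == 102  # lowest of the two tied bins

    def test_zero_red_pixels_excluded(self):
        img = constant_image((64, 64), (100, 80, 60))
        img[4, 4] = (0, 255, 255)
        h = ratio_histogram(img, block_mask(), "G_over_R")
        assert h.counts.sum() == 99


class TestChannelSd:
    def test_constant_channel_zero(self):
        img = constant_image((64, 64), (10, 50, 90))
        assert channel_sd(make_slice(img, img, block_mask()), "GREEN") == 0.0

    def test_two_pixel_population_sd(self):
        img = constant_image((64, 64), (0, 0, 0))
        img[4, 4, 1] = 200
        m = np.zeros((64, 64), bool)
        m[4, 4] = m[4, 5] = True
        assert channel_sd(make_slice(img, img, m), "GREEN") == pytest.approx(100.0)

    def test_single_pixel_missing(self):
        img = constant_image((64, 64), (0, 0, 0))
        m = np.zeros((64, 64), bool)
        m[4, 4] = True
        assert math.isnan(channel_sd(make_slice(img, img, m), "BLUE"))


class TestAstarMean:
    def test_neutral_gray_near_zero(self):
        img = constant_image((64, 64), (128, 128, 128))
        assert abs(astar_mean(make_slice(img, img, block_mask()))) < 0.5

    def test_red_positive_green_negative(self):
        red = constant_image((64, 64), (200, 30, 30))
        green = constant_image((64, 64), (30, 200, 30))
        a_red = astar_mean(make_slice(red, red, block_mask()))
        a_green = astar_mean(make_slice(green, green, block_mask()))
        assert a_red > 0 > a_green

    def test_empty_slice_missing(self):
        img = constant_image((64, 64), (10, 10, 10))
        assert math.isnan(astar_mean(make_slice(img, img, np.zeros((64, 64), bool))))


# ---------------------------------------------------------------------------
# GLCM texture: brute-force pair-enumeration oracle


def glcm_oracle(q, valid, levels, distance, offsets=GLCM_OFFSETS):
    """Enumerate every in-range pixel pair explicitly."""
    glcm = np.zeros((levels, levels), dtype=np.int64)
    h, w = q.shape
    for dr, dc in offsets:
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr * distance, c + dc * distance
                if 0 <= r2 < h and 0 <= c2 < w and valid[r, c] and valid[r2, c2]:
                    glcm[q[r, c], q[r2, c2]] += 1
    return glcm


def correlation_oracle(glcm):
    """Haralick correlation from the raw pair list, no vectorization."""
    pairs = [
        (i, j)
        for i in range(glcm.shape[0])
        for j in range(glcm.shape[1])
        for _ in range(int(glcm[i, j]))
    ]
    n = len(pairs)
    if n == 0:
        return float("nan")
    mu_i = sum(i for i, _ in pairs) / n
    mu_j = sum(j for _, j in pairs) / n
    var_i = sum((i - mu_i) ** 2 for i, _ in pairs) / n
    var_j = sum((j - mu_j) ** 2 for _, j in pairs) / n
    if var_i <= 0 or var_j <= 0:
        return float("nan")
    cov = sum((i - mu_i) * (j - mu_j) for i, j in pairs) / n
    return cov / math.sqrt(var_i * var_j)


class TestGlcm:
    @pytest.mark.parametrize("seed", range(10))
    def test_matrix_and_correlation_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        h, w = rng.integers(4, 17, size=2)
        levels = int(rng.integers(2, 9))
        distance = int(rng.integers(1, 4))
        q = rng.integers(0, levels, size=(h, w))
        valid = rng.random((h, w)) > 0.3
        got = glcm_matrix(q, valid, levels, distance)
        want = glcm_oracle(q, valid, levels, distance)
        assert np.array_equal(got, want)
        gc, oc = haralick_correlation(got), correlation_oracle(want)
        if math.isnan(oc):
            assert math.isnan(gc)
        else:
            assert gc == pytest.approx(oc, abs=1e-12)

    def test_periodic_stripes_match_oracle_exactly(self):
        q = np.tile(np.arange(12) % 2, (12, 1))  # stripes along the 0-deg offset
        valid = np.ones_like(q, bool)
        got = glcm_matrix(q, valid, levels=2, distance=1)
        assert haralick_correlation(got) == pytest.approx(
            correlation_oracle(glcm_oracle(q, valid, 2, 1)), abs=1e-12
        )

    def test_correlation_bounded_by_one(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            q = rng.integers(0, 8, size=(12, 12))
            c = haralick_correlation(glcm_matrix(q, np.ones_like(q, bool), 8, 1))
            if not math.isnan(c):
                assert -1.0 - 1e-12 <= c <= 1.0 + 1e-12

    def test_full_chain_matches_saturation_difference_oracle(self):
        rng = np.random.default_rng(7)
        pre = rng.integers(0, 256, size=(64, 64, 3), dtype=np.uint8)
        post = rng.integers(0, 256, size=(64, 64, 3), dtype=np.uint8)
        mask = np.zeros((64, 64), bool)
        mask[8:24, 8:24] = True
        slc = make_slice(pre, post, mask)
        got = glcm_correlation(slc, levels=8, distance=5)
        diff = rgb2hsv(post[8:24, 8:24] / 255.0)[..., 1] - rgb2hsv(pre[8:24, 8:24] / 255.0)[..., 1]
        q = quantize(diff, np.ones_like(diff, bool), 8)
        want = correlation_oracle(glcm_oracle(q, np.ones_like(q, bool), 8, 5))
        assert got == pytest.approx(want, abs=1e-12)

    def test_constant_difference_is_degenerate(self):
        img = constant_image((64, 64), (100, 80, 60))
        slc = make_slice(img, img.copy(), block_mask(size=20))
        assert math.isnan(glcm_correlation(slc))

    def test_too_small_slice_is_missing(self):
        rng = np.random.default_rng(1)
        pre = rng.integers(0, 256, size=(64, 64, 3), dtype=np.uint8)
        post = rng.integers(0, 256, size=(64, 64, 3), dtype=np.uint8)
        m = np.zeros((64, 64), bool)
        m[10:14, 10:30] = True  # height 4 < distance + 1
        assert math.isnan(glcm_correlation(make_slice(pre, post, m), distance=5))


# ---------------------------------------------------------------------------
# assembly


class TestExtractFeatures:
    def test_identical_constant_slices(self):
        img = constant_image((64, 64), (100, 80, 60))
        v = extract_features(make_slice(img, img.copy(), block_mask(size=20)))
        assert v.d_ave == 0.0 and v.sd_green == 0.0 and v.sd_blue == 0.0
        assert math.isnan(v.glcm_correlation)
        assert not v.is_complete

    def test_abnormal_sector_dominates_normals(self, demo_pair_slices):
        """All five predictor directions on a registered synthetic scene."""
        _, slices = demo_pair_slices
        vecs = {s.sector: extract_features(s) for s in slices}
        abn = vecs[3]  # the CIN2+ sector of the demo scene
        normals = [v for k, v in vecs.items() if k not in (3, 7)]
        assert all(abn.d_ave > v.d_ave for v in normals)
        assert all(abn.sd_green > v.sd_green for v in normals)
        assert all(abn.sd_blue > v.sd_blue for v in normals)
        assert all(abn.glcm_correlation > v.glcm_correlation for v in normals)
        assert all(abn.astar_mean < v.astar_mean for v in normals)

    def test_features_table_shape_and_dropping(self, demo_pair_slices):
        _, slices = demo_pair_slices
        table = features_table([extract_features(s) for s in slices])
        assert len(table) == 12
        assert list(table.columns) == ["patient_id", "sector", *FEATURE_NAMES, "label"]
        img = constant_image((64, 64), (100, 80, 60))
        bad = extract_features(make_slice(img, img.copy(), block_mask(size=20)))
        table2 = features_table(
            [extract_features(s) for s in slices] + [bad], drop_incomplete=True
        )
        assert len(table2) == 12
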