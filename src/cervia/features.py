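"""The five aceto-whitening (VIA) predictors computed per clock slice.

Aceto-white epithelium reflects more green and blue light than the pink
normal cervix, so for each slice we quantify, between the pre- and
post-acetic images:

1. ``d_ave`` — the average shift of the green-to-red and blue-to-red
   intensity-ratio histogram modes, ``(D_G/R + D_B/R) / 2`` where each
   ``D = I_post(mode) - I_pre(mode)`` in bin-index units.  Channel ratios
   make the statistic insensitive to device gain and illumination level.
2. ``sd_green`` / 3. ``sd_blue`` — post-acetic green and blue channel
   standard deviations (whitening broadens these histograms).
4. ``astar_mean`` — mean CIE-Lab a* over the post-acetic slice; whitened
   tissue loses the pink/magenta cast, so a* drops.
5. ``glcm_correlation`` — Haralick correlation of the grey-level
   co-occurrence matrix of the HSV saturation *difference* image
   (post - pre), summed over the four offsets at 0/45/90/135 degrees with
   inter-pixel distance 5; whitened patches change saturation in a
   spatially coherent way, raising the correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv, rgb2lab

from .registration import ClockSlice, UNKNOWN

__all__ = [
    "RatioHistogram",
    "FeatureVector",
    "FEATURE_NAMES",
    "ratio_histogram",
    "ratio_mode_difference",
    "d_ave",
    "channel_sd",
    "astar_mean",
    "glcm_correlation",
    "glcm_matrix",
    "haralick_correlation",
    "extract_features",
    "features_table",
]

FEATURE_NAMES = ("d_ave", "sd_green", "sd_blue", "astar_mean", "glcm_correlation")

#: ratio histograms span [0, 2] in 256 uniform bins; ratios above 2 land in
#: the top bin (pink tissue sits below 1, whitened tissue approaches 1)
RATIO_RANGE = (0.0, 2.0)
RATIO_BINS = 256
MIN_PIXELS = 50

_CHANNEL = {"G_over_R": 1, "B_over_R": 2, "GREEN": 1, "BLUE": 2}

#: row/col offsets of the four co-occurrence angles at unit distance,
#: in the usual convention (0, 45, 90, 135 degrees)
GLCM_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass(frozen=True)
class RatioHistogram:
    """Histogram of a per-pixel channel ratio over the valid slice pixels."""

    channel_pair: str
    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def mode_index(self) -> int:
        # deterministic tie-break: the lowest bin attaining the max count
        return int(np.argmax(self.counts))


@dataclass(frozen=True)
class FeatureVector:
    """The five VIA predictors for one clock slice (NaN = missing)."""

    patient_id: str
    sector: int
    d_ave: float
    sd_green: float
    sd_blue: float
    astar_mean: float
    glcm_correlation: float
    label: str = UNKNOWN

    @property
    def is_complete(self) -> bool:
        return not any(
            math.isnan(getattr(self, f)) for f in FEATURE_NAMES
        )


def _valid_ratio_pixels(img: np.ndarray, mask: np.ndarray, channel: int) -> np.ndarray:
    rgb = img[mask].astype(np.float64)
    r = rgb[:, 0]
    ok = r > 0
    return rgb[ok, channel] / r[ok]


def ratio_histogram(
    img: np.ndarray,
    mask: np.ndarray,
    channel_pair: str,
    bins: int = RATIO_BINS,
) -> RatioHistogram:
    """Histogram G/R or B/R over unmasked pixels with R > 0.

    Ratios above the fixed range are clipped into the top bin so every valid
    pixel is counted exactly once.
    """
    ratios = _valid_ratio_pixels(img, mask, _CHANNEL[channel_pair])
    lo, hi = RATIO_RANGE
    width = (hi - lo) / bins
    idx = np.clip(np.floor((ratios - lo) / width).astype(int), 0, bins - 1)
    counts = np.bincount(idx, minlength=bins)
    edges = lo + width * np.arange(bins + 1)
    return RatioHistogram(channel_pair=channel_pair, bin_edges=edges, counts=counts)


def ratio_mode_difference(
    slc: ClockSlice,
    channel_pair: str,
    bins: int = RATIO_BINS,
    min_pixels: int = MIN_PIXELS,
) -> float:
    """Signed histogram-mode shift ``I_post(mode) - I_pre(mode)`` in bins.

    Returns NaN when either phase has fewer than ``min_pixels`` valid
    (unmasked, R > 0) pixels.
    """
    pre = ratio_histogram(slc.pre, slc.mask, channel_pair, bins)
    post = ratio_histogram(slc.post, slc.mask, channel_pair, bins)
    if pre.counts.sum() < min_pixels or post.counts.sum() < min_pixels:
        return float("nan")
    return float(post.mode_index - pre.mode_index)


def d_ave(slc: ClockSlice, bins: int = RATIO_BINS) -> float:
    """Average of the G/R and B/R mode shifts (bin-index units)."""
    dg = ratio_mode_difference(slc, "G_over_R", bins)
    db = ratio_mode_difference(slc, "B_over_R", bins)
    return (dg + db) / 2.0


def channel_sd(slc: ClockSlice, channel: str) -> float:
    """Population SD of the post-acetic green or blue channel over the mask."""
    vals = slc.post[slc.mask, _CHANNEL[channel]].astype(np.float64)
    if vals.size < 2:
        return float("nan")
    return float(vals.std(ddof=0))


def astar_mean(slc: ClockSlice) -> float:
    """Mean CIE-Lab a* (sRGB, D65 white) over the post-acetic slice pixels."""
    if not slc.mask.any():
        return float("nan")
    rows, cols = np.nonzero(slc.mask)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    lab = rgb2lab(slc.post[r0:r1, c0:c1].astype(np.float64) / 255.0)
    return float(lab[..., 1][slc.mask[r0:r1, c0:c1]].mean())


# ---------------------------------------------------------------------------
# GLCM texture on the saturation-difference image


def _saturation(img: np.ndarray) -> np.ndarray:
    return rgb2hsv(img.astype(np.float64) / 255.0)[..., 1]


def quantize(values: np.ndarray, valid: np.ndarray, levels: int) -> np.ndarray | None:
    """Linearly quantize valid values to 0..levels-1 over their own range.

    Returns None when the valid values are constant (degenerate texture).
    """
    v = values[valid]
    lo, hi = v.min(), v.max()
    if hi <= lo:
        return None
    q = np.floor((values - lo) / (hi - lo) * levels).astype(int)
    return np.clip(q, 0, levels - 1)


def glcm_matrix(
    quantized: np.ndarray,
    valid: np.ndarray,
    levels: int,
    distance: int,
    offsets=GLCM_OFFSETS,
) -> np.ndarray:
    """Sum of the four directional co-occurrence matrices.

    Each offset matrix is accumulated non-symmetrically, counting only the
    pixel pairs where both endpoints are valid, then the four are summed.
    """
    glcm = np.zeros((levels, levels), dtype=np.int64)
    h, w = quantized.shape
    for dr, dc in offsets:
        dr, dc = dr * distance, dc * distance
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        src = quantized[r0:r1, c0:c1]
        dst = quantized[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ok = valid[r0:r1, c0:c1] & valid[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        np.add.at(glcm, (src[ok], dst[ok]), 1)
    return glcm


def haralick_correlation(glcm: np.ndarray) -> float:
    """Haralick correlation of a (possibly unnormalized) co-occurrence matrix.

    ``sum_ij (i - mu_i)(j - mu_j) p(i, j) / (sigma_i sigma_j)``; NaN when
    either marginal is degenerate (zero variance).
    """
    total = glcm.sum()
    if total == 0:
        return float("nan")
    p = glcm.astype(np.float64) / total
    i = np.arange(p.shape[0], dtype=np.float64)
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = (i * pi).sum()
    mu_j = (i * pj).sum()
    var_i = ((i - mu_i) ** 2 * pi).sum()
    var_j = ((i - mu_j) ** 2 * pj).sum()
    if var_i <= 0 or var_j <= 0:
        return float("nan")
    cov = ((i[:, None] - mu_i) * (i[None, :] - mu_j) * p).sum()
    return float(cov / math.sqrt(var_i * var_j))


def glcm_correlation(
    slc: ClockSlice,
    levels: int = 8,
    distance: int = 5,
) -> float:
    """Haralick correlation of the S-channel difference image for one slice.

    The HSV saturation of pre and post is differenced on the slice bounding
    box; out-of-mask pixels are invalid and never paired.  NaN for slices
    too small for the offset distance or with constant difference.
    """
    if not slc.mask.any():
        return float("nan")
    rows, cols = np.nonzero(slc.mask)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    if (r1 - r0) <= distance or (c1 - c0) <= distance:
        return float("nan")
    diff = (
        _saturation(slc.post[r0:r1, c0:c1]) - _saturation(slc.pre[r0:r1, c0:c1])
    )
    valid = slc.mask[r0:r1, c0:c1]
    q = quantize(diff, valid, levels)
    if q is None:
        return float("nan")
    glcm = glcm_matrix(q, valid, levels, distance)
    return haralick_correlation(glcm)


def extract_features(
    slc: ClockSlice,
    glcm_levels: int = 8,
    glcm_distance: int = 5,
    ratio_bins: int = RATIO_BINS,
) -> FeatureVector:
    """Assemble the five predictors (plus label) for one clock slice."""
    return FeatureVector(
        patient_id=slc.patient_id,
        sector=slc.sector,
        d_ave=d_ave(slc, ratio_bins),
        sd_green=channel_sd(slc, "GREEN"),
        sd_blue=channel_sd(slc, "BLUE"),
        astar_mean=astar_mean(slc),
        glcm_correlation=glcm_correlation(slc, glcm_levels, glcm_distance),
        label=slc.label,
    )


def features_table(vectors, drop_incomplete: bool = False) -> pd.DataFrame:
    """Stack feature vectors into the standard feature table."""
    rows = [
        {
            "patient_id": v.patient_id,
            "sector": v.sector,
            **{f: getattr(v, f) for f in FEATURE_NAMES},
            "label": v.label,
        }
        for v in vectors
    ]
    df = pd.DataFrame(
        rows,
        columns=["patient_id", "sector", *FEATURE_NAMES, "label"],
    )
    if drop_incomplete and len(df):
        df = df.dropna(subset=list(FEATURE_NAMES)).reset_index(drop=True)
    return df
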