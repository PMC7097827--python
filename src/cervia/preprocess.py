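"""Specular-reflection removal and red-channel bit-plane ROI segmentation.

The preprocessing chain for each cervicogram is: (1) detect saturated
specular highlights at an intensity threshold of 60% of the 8-bit range,
(2) inpaint them smoothly from their neighbourhood, (3) segment the
ectocervix region of interest from the two most significant bit-planes of
the red channel, and (4) intersect the pre- and post-acetic ROI masks so
that only tissue visible in both images of a pair is analysed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.ndimage import binary_fill_holes, distance_transform_edt
from scipy.spatial import cKDTree
from skimage import morphology
from skimage.measure import label as cc_label

__all__ = [
    "Phase",
    "MaskKind",
    "Cervicogram",
    "BinaryMask",
    "detect_specular",
    "inpaint_specular",
    "bitplane_roi",
    "combine_roi",
]


class Phase(str, Enum):
    PRE = "PRE"
    POST = "POST"


class MaskKind(str, Enum):
    SPECULAR = "SPECULAR"
    ROI_PRIMARY = "ROI_PRIMARY"
    ROI_COMBINED = "ROI_COMBINED"


@dataclass
class Cervicogram:
    """An 8-bit RGB cervix image with acquisition phase and patient id."""

    pixels: np.ndarray
    phase: Phase = Phase.PRE
    patient_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) RGB array")
        if px.shape[0] < 64 or px.shape[1] < 64:
            raise ValueError("image must be at least 64x64")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class BinaryMask:
    """A boolean mask tied to an image's geometry."""

    pixels: np.ndarray
    kind: MaskKind

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _as_pixels(img) -> np.ndarray:
    return img.pixels if isinstance(img, Cervicogram) else np.asarray(img)


def detect_specular(img, threshold_fraction: float = 0.6) -> BinaryMask:
    """Flag saturated specular highlights.

    A pixel is specular when its brightest channel reaches
    ``threshold_fraction`` of the 8-bit maximum; the per-pixel channel max is
    used because true specular highlights saturate every channel and the max
    is robust to the tissue's strong red cast.
    """
    if not 0.0 < threshold_fraction <= 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1]")
    px = _as_pixels(img)
    gray = px.max(axis=2).astype(np.float64)
    return BinaryMask(gray >= threshold_fraction * 255.0, MaskKind.SPECULAR)


def inpaint_specular(img, sr_mask: BinaryMask, radius: float = 5.0) -> Cervicogram:
    """Fill specular pixels by inverse-distance interpolation of nearby tissue.

    Each masked pixel is replaced by the 1/d^2-weighted mean of unmasked
    pixels within ``radius``; masked pixels with no unmasked neighbour in
    range fall back to their nearest unmasked pixel, so no saturated value
    survives inside the mask.  Pixels outside the mask are untouched.
    """
    px = _as_pixels(img).astype(np.float64)
    mask = sr_mask.pixels
    if mask.shape != px.shape[:2]:
        raise ValueError("mask shape does not match image")
    if not mask.any():
        out = px
    elif mask.all():
        raise ValueError("mask covers the whole image: nothing to interpolate from")
    else:
        out = px.copy()
        valid = ~mask
        valid_coords = np.argwhere(valid)
        tree = cKDTree(valid_coords)
        hole_coords = np.argwhere(mask)
        neighbours = tree.query_ball_point(hole_coords, r=radius)
        # nearest-valid fallback for deep interior pixels
        _, (ni, nj) = distance_transform_edt(mask, return_indices=True)
        vals = px[valid]
        for (r, c), idx in zip(hole_coords, neighbours):
            if idx:
                pts = valid_coords[idx]
                d2 = (pts[:, 0] - r) ** 2.0 + (pts[:, 1] - c) ** 2.0
                wgt = 1.0 / d2
                out[r, c] = (wgt[:, None] * vals[idx]).sum(axis=0) / wgt.sum()
            else:
                out[r, c] = px[ni[r, c], nj[r, c]]
    res = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    phase = img.phase if isinstance(img, Cervicogram) else Phase.PRE
    pid = img.patient_id if isinstance(img, Cervicogram) else ""
    return Cervicogram(res, phase=phase, patient_id=pid)


def bitplane_roi(
    img,
    planes: tuple[int, ...] = (6, 7),
    combine: str = "or",
    clean: bool = True,
    closing_radius: int = 5,
) -> BinaryMask:
    """Segment the ectocervix from high-order red-channel bit-planes.

    The red channel is sliced into its eight bit-planes; the two most
    significant planes (bits 6 and 7, i.e. red >= 64) mark the bright red
    ectocervix.  ``combine`` selects the permissive union (``"or"``, the
    default) or the strict intersection (``"and"``, red >= 192) of the
    selected planes.  With ``clean`` the raw speckled mask is closed with a
    small disk, reduced to its largest connected component, and hole-filled.
    """
    if combine not in ("or", "and"):
        raise ValueError("combine must be 'or' or 'and'")
    px = _as_pixels(img)
    red = px[..., 0]
    bits = [(red >> p) & 1 for p in planes]
    raw = np.zeros(red.shape, dtype=bool) if combine == "or" else np.ones(red.shape, dtype=bool)
    for b in bits:
        raw = (raw | (b > 0)) if combine == "or" else (raw & (b > 0))
    if not clean or not raw.any():
        return BinaryMask(raw, MaskKind.ROI_PRIMARY)
    mask = morphology.closing(raw, morphology.disk(closing_radius))
    lab = cc_label(mask, connectivity=2)
    if lab.max() > 0:
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        mask = lab == sizes.argmax()
    mask = binary_fill_holes(mask)
    return BinaryMask(mask, MaskKind.ROI_PRIMARY)


def combine_roi(mask_pre: BinaryMask, mask_post: BinaryMask) -> BinaryMask:
    """Intersect the pre- and post-acetic ROI masks (logical AND)."""
    if mask_pre.shape != mask_post.shape:
        raise ValueError("ROI masks must share a shape")
    return BinaryMask(mask_pre.pixels & mask_post.pixels, MaskKind.ROI_COMBINED)
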