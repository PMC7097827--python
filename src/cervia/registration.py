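"""Fiducial-based rigid registration and 12-sector clock slicing.

Each image of a pre/post pair carries three manually placed fiducials: the
cervix centre and the two endpoints of the cervical os.  Registration
rotates each image about its own centre fiducial so the os line becomes
horizontal (with ``os_a`` mapped to the left), then translates both centres
to the centre of a shared canvas — a rigid transform only, no scaling.  The
combined ROI is recomputed from the transformed per-image masks.

The registered pair is then sliced into 12 clock-position sectors about the
centre fiducial, matching how excised tissue is sectioned for histopathology:
sector ``k`` is the 30-degree arc centred on clock hour ``k``, with hour 12
pointing straight up and hours increasing clockwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import EuclideanTransform, warp

from .preprocess import BinaryMask, Cervicogram, MaskKind, bitplane_roi, combine_roi
from .synthetic import FiducialSet, Grade, VIA_NEG, VIA_POS, sector_index

__all__ = [
    "FiducialSet",
    "CervicogramPair",
    "ClockSlice",
    "register_pair",
    "slice_clock",
    "attach_labels",
]

UNKNOWN = "UNKNOWN"


@dataclass
class CervicogramPair:
    """A registered pre/post pair sharing a canvas, ROI, and fiducials."""

    pre: Cervicogram
    post: Cervicogram
    roi: BinaryMask
    fiducials: FiducialSet

    def __post_init__(self) -> None:
        if not (self.pre.shape == self.post.shape == self.roi.shape):
            raise ValueError("pre, post and roi must share dimensions")


@dataclass
class ClockSlice:
    """One 30-degree sector of a registered pair.

    ``pre`` and ``post`` are the full registered images (shared references);
    ``mask`` restricts them to this sector's intersection with the ROI.
    """

    patient_id: str
    sector: int
    pre: np.ndarray
    post: np.ndarray
    mask: np.ndarray
    label: str = UNKNOWN
    error: str | None = None

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def _os_angle(fid: FiducialSet) -> float:
    """Angle (radians) of the os line os_a -> os_b in image xy coordinates."""
    dx = fid.os_b[0] - fid.os_a[0]
    dy = fid.os_b[1] - fid.os_a[1]
    if dx == 0 and dy == 0:
        raise ValueError("os endpoints coincide")
    return math.atan2(dy, dx)


def _rigid_transform(fid: FiducialSet, out_center: tuple[float, float]) -> EuclideanTransform:
    """Forward map: rotate by -os_angle about the centre fiducial, then
    translate the centre to ``out_center``."""
    alpha = _os_angle(fid)
    ca, sa = math.cos(-alpha), math.sin(-alpha)
    cx, cy = fid.center
    ox, oy = out_center
    tx = ox - (ca * cx - sa * cy)
    ty = oy - (sa * cx + ca * cy)
    return EuclideanTransform(
        matrix=np.array([[ca, -sa, tx], [sa, ca, ty], [0.0, 0.0, 1.0]])
    )


def _apply(tf: EuclideanTransform, pt: tuple[float, float]) -> tuple[float, float]:
    x, y = tf(np.asarray(pt, dtype=float)[None, :])[0]
    return (float(x), float(y))


def register_pair(
    pre: Cervicogram,
    post: Cervicogram,
    fid_pre: FiducialSet,
    fid_post: FiducialSet,
    roi_pre: BinaryMask | None = None,
    roi_post: BinaryMask | None = None,
) -> CervicogramPair:
    """Rigidly register a pre/post pair from the three fiducials.

    Each image is rotated about its own centre fiducial by the negative of
    its os-line angle and translated so both centres coincide at the centre
    of the output canvas (sized to the larger of the two inputs).  Images are
    resampled bilinearly, masks with nearest-neighbour so they stay binary;
    pixels warped in from outside the source frame are excluded from the ROI.
    """
    fid_pre.validate(pre.shape)
    fid_post.validate(post.shape)
    if roi_pre is None:
        roi_pre = bitplane_roi(pre)
    if roi_post is None:
        roi_post = bitplane_roi(post)

    h = max(pre.shape[0], post.shape[0])
    w = max(pre.shape[1], post.shape[1])
    out_center = ((w - 1) / 2.0, (h - 1) / 2.0)

    warped: dict[str, np.ndarray] = {}
    for name, img, roi, fid in (
        ("pre", pre, roi_pre, fid_pre),
        ("post", post, roi_post, fid_post),
    ):
        tf = _rigid_transform(fid, out_center)
        wimg = warp(
            img.pixels.astype(np.float64),
            tf.inverse,
            output_shape=(h, w),
            order=1,
            cval=0.0,
            preserve_range=True,
        )
        warped[name] = np.clip(np.rint(wimg), 0, 255).astype(np.uint8)
        wmask = warp(
            roi.pixels.astype(np.float64),
            tf.inverse,
            output_shape=(h, w),
            order=0,
            cval=0.0,
            preserve_range=True,
        )
        warped[name + "_roi"] = wmask > 0.5

    tf_pre = _rigid_transform(fid_pre, out_center)
    os_a = _apply(tf_pre, fid_pre.os_a)
    os_b = _apply(tf_pre, fid_pre.os_b)
    fid_out = FiducialSet(center=out_center, os_a=os_a, os_b=os_b)

    roi = combine_roi(
        BinaryMask(warped["pre_roi"], MaskKind.ROI_PRIMARY),
        BinaryMask(warped["post_roi"], MaskKind.ROI_PRIMARY),
    )
    return CervicogramPair(
        pre=Cervicogram(warped["pre"], phase=pre.phase, patient_id=pre.patient_id),
        post=Cervicogram(warped["post"], phase=post.phase, patient_id=post.patient_id),
        roi=roi,
        fiducials=fid_out,
    )


def slice_clock(pair: CervicogramPair) -> list[ClockSlice]:
    """Partition the pair's ROI into 12 clock-position slices.

    Every true ROI pixel is assigned to exactly one sector by its angle
    about the centre fiducial; 12 slices are always returned, possibly with
    empty masks.  An empty ROI flags an error on all slices.
    """
    h, w = pair.roi.shape
    cx, cy = pair.fiducials.center
    yy, xx = np.mgrid[0:h, 0:w]
    theta = np.mod(np.degrees(np.arctan2(xx - cx, -(yy - cy))), 360.0)
    sectors = sector_index(theta)
    empty = not pair.roi.pixels.any()
    out = []
    for k in range(1, 13):
        out.append(
            ClockSlice(
                patient_id=pair.pre.patient_id,
                sector=k,
                pre=pair.pre.pixels,
                post=pair.post.pixels,
                mask=(sectors == k) & pair.roi.pixels,
                error="empty ROI" if empty else None,
            )
        )
    return out


def attach_labels(slices: list[ClockSlice], grades) -> list[ClockSlice]:
    """Attach binary screening labels from per-sector histopathology grades.

    ``grades`` maps clock index -> grade; grades NORMAL and CIN1 become
    VIA_NEG (only CIN2+ warrants treatment), CIN2PLUS becomes VIA_POS.
    Sectors without a grade keep the UNKNOWN label and are excluded from
    training downstream.
    """
    out = []
    for s in slices:
        g = grades.get(s.sector)
        if g is None:
            out.append(replace(s, label=UNKNOWN))
            continue
        g = Grade(g)
        out.append(replace(s, label=VIA_POS if g is Grade.CIN2PLUS else VIA_NEG))
    return out
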