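"""Seeded synthetic cervicogram pairs with per-clock-sector ground truth.

Real aceto-whitening screening data is clinical and not publicly deposited,
so every downstream stage of the pipeline is exercised on parametric scenes
that reproduce the statistical structure the features assume:

* a pinkish elliptical ectocervix on a dark background, with a dimmer
  vaginal-wall annulus so red-channel bit-plane masking is non-trivial;
* a dark cervical-os slit through the centre whose endpoints, together with
  the centre, form the three manual fiducials used for registration;
* saturated specular highlights (8-bit maximum in all channels);
* post-acetic aceto-white patches confined to chosen clock sectors, rendered
  as a multiplicative green/blue gain plus a smooth speckle texture — this
  raises the green/blue-to-red ratio modes and channel SDs, lowers CIE-Lab
  a*, and gives the saturation-difference image spatially correlated texture,
  which is exactly the direction of every selected predictor.

Sectors are painted in the *registered* clock frame (the frame in which the
os line is horizontal), so that after fiducial registration sector ``k`` of
the image coincides with ground-truth sector ``k``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "Grade",
    "SceneSpec",
    "GroundTruth",
    "PatientRecord",
    "generate_scene",
    "generate_cohort",
    "write_cohort",
    "sector_mask",
]


class Grade(str, Enum):
    """Histopathology grade of one clock sector."""

    NORMAL = "NORMAL"
    CIN1 = "CIN1"
    CIN2PLUS = "CIN2PLUS"


#: binary screening labels; only CIN2+ is treat-worthy, so CIN1 maps negative
VIA_NEG = "VIA_NEG"
VIA_POS = "VIA_POS"

_BACKGROUND_RGB = (25.0, 18.0, 20.0)
_WALL_RGB = (55.0, 38.0, 42.0)  # red < 64: excluded by the bit-plane ROI
#: the os slit is rendered as moderately darkened tissue (fraction of the
#: cervix colour) so it is visible without dominating within-sector variance
_OS_SHADE = 0.8
#: multiplicative G/B gain per unit whitening strength
_WHITEN_GAIN = 0.55
#: amplitude (8-bit units) of the smooth speckle texture per unit strength
_TEXTURE_AMP = 10.0
#: CIN1 sectors whiten at this fraction of the CIN2+ strength
_CIN1_SCALE = 0.3


@dataclass(frozen=True)
class SceneSpec:
    """Parametric description of one synthetic pre/post cervicogram pair.

    Parameters
    ----------
    image_size : int
        Side of the square 8-bit RGB canvas, pixels.
    cervix_center : (float, float)
        Ellipse centre in ``(x, y)`` pixel coordinates (x = column).
    cervix_radii : (float, float)
        Ellipse semi-axes ``(rx, ry)`` in pixels.
    os_half_length : float
        Half-length of the cervical-os slit, pixels.
    abnormal_sectors : frozenset of int
        Clock indices (1..12) rendered as CIN2+ aceto-white.
    cin1_sectors : frozenset of int
        Clock indices rendered as CIN1 (whitening scaled by 0.3); the
        confusable class that the binary labelling treats as normal.
    whitening_strength : float
        Unitless 0..1 green/blue gain in abnormal sectors post-acetic.
    n_specular_spots : int
        Saturated specular disks placed per image (fresh positions pre/post).
    illumination_gain : float
        Global multiplicative intensity factor applied to both images.
    noise_sd : float
        SD of i.i.d. Gaussian pixel noise, 8-bit units, fresh per image.
    os_angle_deg : float
        Orientation of the os line in the *unregistered* image; registration
        rotates it back to horizontal.
    seed : int
        Seed for every random element of the scene.
    """

    image_size: int = 512
    cervix_center: tuple[float, float] | None = None
    cervix_radii: tuple[float, float] | None = None
    os_half_length: float | None = None
    abnormal_sectors: frozenset[int] = frozenset()
    cin1_sectors: frozenset[int] = frozenset()
    whitening_strength: float = 0.5
    n_specular_spots: int = 6
    illumination_gain: float = 1.0
    noise_sd: float = 2.0
    os_angle_deg: float = 0.0
    cervix_rgb: tuple[float, float, float] = (140.0, 92.0, 100.0)
    seed: int = 0

    @property
    def center(self) -> tuple[float, float]:
        if self.cervix_center is None:
            c = (self.image_size - 1) / 2.0
            return (c, c)
        return self.cervix_center

    @property
    def radii(self) -> tuple[float, float]:
        # defaults scale with the canvas: ectocervix fills ~1/3 of the frame
        if self.cervix_radii is None:
            return (0.33 * self.image_size, 0.27 * self.image_size)
        return self.cervix_radii

    @property
    def os_half(self) -> float:
        if self.os_half_length is None:
            return 0.12 * self.image_size
        return self.os_half_length

    def validate(self) -> None:
        secs = set(self.abnormal_sectors) | set(self.cin1_sectors)
        if not secs <= set(range(1, 13)):
            raise ValueError("abnormal/cin1 sectors must be clock indices in 1..12")
        if not 0.0 <= self.whitening_strength <= 1.0:
            raise ValueError("whitening_strength must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        rx, ry = self.radii
        if rx <= 0 or ry <= 0:
            raise ValueError("cervix_radii must be positive")
        cx, cy = self.center
        if not (rx <= cx <= self.image_size - 1 - rx and ry <= cy <= self.image_size - 1 - ry):
            raise ValueError("cervix ellipse must fit inside image bounds")
        if self.os_half <= 0:
            raise ValueError("os_half_length must be positive")
        if self.n_specular_spots < 0:
            raise ValueError("n_specular_spots must be >= 0")
        if self.illumination_gain <= 0:
            raise ValueError("illumination_gain must be positive")


@dataclass(frozen=True)
class FiducialSet:
    """The three manual registration fiducials, in (x, y) pixels.

    ``center`` is the cervix centre; ``os_a``/``os_b`` are the two endpoints
    of the cervical os.  By convention ``os_a`` is the endpoint that ends up
    on the left after registration.
    """

    center: tuple[float, float]
    os_a: tuple[float, float]
    os_b: tuple[float, float]

    def validate(self, shape: tuple[int, int] | None = None) -> None:
        if tuple(self.os_a) == tuple(self.os_b):
            raise ValueError("os endpoints must be distinct")
        if shape is not None:
            h, w = shape[:2]
            for x, y in (self.center, self.os_a, self.os_b):
                if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
                    raise ValueError("fiducial outside image bounds")

    def to_json(self) -> str:
        return json.dumps(
            {"center": list(self.center), "os": [list(self.os_a), list(self.os_b)]}
        )

    @classmethod
    def from_json(cls, text: str) -> "FiducialSet":
        d = json.loads(text)
        (a, b) = d["os"]
        return cls(center=tuple(d["center"]), os_a=tuple(a), os_b=tuple(b))


@dataclass(frozen=True)
class GroundTruth:
    """Per-sector histopathology grades and the derived binary labels."""

    sector_labels: dict[int, Grade]

    @property
    def binary_labels(self) -> dict[int, str]:
        # CIN2+ is abnormal; normal and CIN1 are screened negative
        return {
            k: (VIA_POS if g is Grade.CIN2PLUS else VIA_NEG)
            for k, g in self.sector_labels.items()
        }


@dataclass
class PatientRecord:
    """One simulated patient: the image pair plus annotations."""

    patient_id: str
    spec: SceneSpec
    pre: np.ndarray
    post: np.ndarray
    fiducials: FiducialSet
    truth: GroundTruth


# ---------------------------------------------------------------------------
# geometry helpers

def _clock_theta(shape: tuple[int, int], center: tuple[float, float],
                 rotation_deg: float = 0.0) -> np.ndarray:
    """Clock angle (degrees in [0, 360)) of every pixel about ``center``.

    0 deg points straight up in the *registered* frame and angles grow
    clockwise; ``rotation_deg`` is the scene's os-line orientation, so that
    painting with this angle matches the frame registration will produce.
    """
    h, w = shape[:2]
    cx, cy = center
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - cx
    dy = yy - cy
    if rotation_deg:
        phi = np.deg2rad(rotation_deg)
        dxr = dx * np.cos(phi) + dy * np.sin(phi)
        dyr = -dx * np.sin(phi) + dy * np.cos(phi)
        dx, dy = dxr, dyr
    theta = np.degrees(np.arctan2(dx, -dy))
    return np.mod(theta, 360.0)


def sector_index(theta_deg: np.ndarray) -> np.ndarray:
    """Map clock angle to sector 1..12 (sector k spans [30k-15, 30k+15))."""
    k = np.floor_divide(np.mod(theta_deg + 15.0, 360.0), 30.0).astype(int)
    k = np.mod(k, 12)
    return np.where(k == 0, 12, k)


def sector_mask(spec: SceneSpec, sector: int) -> np.ndarray:
    """Analytic mask of one clock sector intersected with the cervix ellipse."""
    theta = _clock_theta((spec.image_size, spec.image_size), spec.center,
                         rotation_deg=spec.os_angle_deg)
    return (sector_index(theta) == sector) & _ellipse_mask(spec)


def _ellipse_mask(spec: SceneSpec, scale: float = 1.0) -> np.ndarray:
    h = w = spec.image_size
    cx, cy = spec.center
    rx, ry = spec.radii
    yy, xx = np.mgrid[0:h, 0:w]
    return ((xx - cx) / (rx * scale)) ** 2 + ((yy - cy) / (ry * scale)) ** 2 <= 1.0


# ---------------------------------------------------------------------------
# scene rendering

def generate_scene(
    spec: SceneSpec,
) -> tuple[np.ndarray, np.ndarray, FiducialSet, GroundTruth]:
    """Render one seeded pre/post pair.

    Returns ``(pre_image, post_image, fiducials, truth)`` where both images
    are ``uint8`` RGB arrays of shape ``(image_size, image_size, 3)``.  The
    post image differs from the pre image only inside whitened sectors, plus
    fresh specular spots and noise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h = w = spec.image_size
    cx, cy = spec.center

    base = np.empty((h, w, 3), dtype=np.float64)
    base[:] = _BACKGROUND_RGB

    wall = _ellipse_mask(spec, 1.45) & ~_ellipse_mask(spec, 1.12)
    base[wall] = _WALL_RGB

    cervix = _ellipse_mask(spec)
    base[cervix] = spec.cervix_rgb

    # smooth shared shading so tissue is not perfectly flat
    shade = gaussian_filter(rng.standard_normal((h, w)), sigma=24.0)
    sd = shade.std()
    if sd > 0:
        # bounded so tissue stays clear of the 60% saturation threshold
        shade = np.clip(shade / sd * 4.0, -8.0, 8.0)
    base[cervix] += shade[cervix, None]

    # cervical os slit; its endpoints are the registration fiducials
    phi = np.deg2rad(spec.os_angle_deg)
    ux, uy = np.cos(phi), np.sin(phi)
    yy, xx = np.mgrid[0:h, 0:w]
    t = (xx - cx) * ux + (yy - cy) * uy          # along-slit coordinate
    d = -(xx - cx) * uy + (yy - cy) * ux         # across-slit coordinate
    slit = (np.abs(t) <= spec.os_half) & (np.abs(d) <= 2.5) & cervix
    base[slit] = tuple(_OS_SHADE * c for c in spec.cervix_rgb)

    fiducials = FiducialSet(
        center=(cx, cy),
        os_a=(cx - spec.os_half * ux, cy - spec.os_half * uy),
        os_b=(cx + spec.os_half * ux, cy + spec.os_half * uy),
    )

    pre = base.copy()
    post = base.copy()

    theta = _clock_theta((h, w), (cx, cy), rotation_deg=spec.os_angle_deg)
    sectors = sector_index(theta)
    for k in range(1, 13):
        if k in spec.abnormal_sectors:
            strength = spec.whitening_strength
        elif k in spec.cin1_sectors:
            strength = spec.whitening_strength * _CIN1_SCALE
        else:
            continue
        m = (sectors == k) & cervix & ~slit
        gain = 1.0 + _WHITEN_GAIN * strength
        post[m, 1] *= gain
        post[m, 2] *= gain
        # smooth speckle: spatially correlated texture in the whitened patch
        tex = gaussian_filter(rng.standard_normal((h, w)), sigma=6.0)
        tsd = tex.std()
        if tsd > 0:
            tex = np.clip(tex / tsd, -2.0, 2.0)
        post[m, 1] += _TEXTURE_AMP * strength * tex[m]
        post[m, 2] += _TEXTURE_AMP * strength * tex[m]

    pre *= spec.illumination_gain
    post *= spec.illumination_gain

    for img in (pre, post):
        _add_specular(img, spec, rng)
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=img.shape)

    pre_u8 = np.clip(np.rint(pre), 0, 255).astype(np.uint8)
    post_u8 = np.clip(np.rint(post), 0, 255).astype(np.uint8)

    labels = {}
    for k in range(1, 13):
        if k in spec.abnormal_sectors:
            labels[k] = Grade.CIN2PLUS
        elif k in spec.cin1_sectors:
            labels[k] = Grade.CIN1
        else:
            labels[k] = Grade.NORMAL
    return pre_u8, post_u8, fiducials, GroundTruth(labels)


def _add_specular(img: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> None:
    """Stamp saturated disks inside the cervix (8-bit max in all channels)."""
    h, w = img.shape[:2]
    cx, cy = spec.center
    rx, ry = spec.radii
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(spec.n_specular_spots):
        ang = rng.uniform(0, 2 * np.pi)
        rad = np.sqrt(rng.uniform(0, 0.55))
        sx = cx + rad * rx * np.cos(ang)
        sy = cy + rad * ry * np.sin(ang)
        r = rng.uniform(2.5, 5.5)
        disk = (xx - sx) ** 2 + (yy - sy) ** 2 <= r**2
        img[disk] = 255.0


# ---------------------------------------------------------------------------
# cohorts

def generate_cohort(
    n_patients: int = 20,
    fraction_abnormal_patients: float = 0.6,
    sectors_per_abnormal: tuple[int, int] = (2, 6),
    seed: int = 0,
    *,
    image_size: int = 512,
    whitening_strength: float = 0.5,
    noise_sd: float = 2.0,
    n_specular_spots: int = 6,
) -> list[PatientRecord]:
    """Simulate a labelled cohort of pre/post pairs.

    Exactly ``round(fraction * n)`` patients receive at least one CIN2+
    sector; the remainder are negative at every clock position but may carry
    CIN1 sectors, mirroring the design in which low-grade lesions are
    screened as normal.  Per-patient seeds are derived deterministically from
    the master seed.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if not 0.0 <= fraction_abnormal_patients <= 1.0:
        raise ValueError("fraction_abnormal_patients must lie in [0, 1]")
    lo, hi = sectors_per_abnormal
    if not (1 <= lo <= hi <= 12):
        raise ValueError("sectors_per_abnormal must satisfy 1 <= lo <= hi <= 12")

    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_patients)
    n_abnormal = int(round(fraction_abnormal_patients * n_patients))
    abnormal_ids = set(rng.permutation(n_patients)[:n_abnormal].tolist())

    records: list[PatientRecord] = []
    for i in range(n_patients):
        prng = np.random.default_rng(child_seeds[i])
        if i in abnormal_ids:
            n_pos = int(prng.integers(lo, hi + 1))
            secs = prng.permutation(np.arange(1, 13))
            abnormal = frozenset(int(s) for s in secs[:n_pos])
            n_cin1 = int(prng.integers(0, 3))
            cin1 = frozenset(int(s) for s in secs[n_pos : n_pos + n_cin1])
        else:
            abnormal = frozenset()
            n_cin1 = int(prng.integers(0, 4))
            cin1 = frozenset(
                int(s) for s in prng.permutation(np.arange(1, 13))[:n_cin1]
            )
        spec = SceneSpec(
            image_size=image_size,
            abnormal_sectors=abnormal,
            cin1_sectors=cin1,
            whitening_strength=whitening_strength,
            noise_sd=noise_sd,
            n_specular_spots=n_specular_spots,
            os_angle_deg=float(prng.uniform(-80.0, 80.0)),
            seed=int(child_seeds[i]),
        )
        pre, post, fid, truth = generate_scene(spec)
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:03d}",
                spec=spec,
                pre=pre,
                post=post,
                fiducials=fid,
                truth=truth,
            )
        )
    return records


def write_cohort(records: Sequence[PatientRecord], out_dir: str | Path) -> pd.DataFrame:
    """Persist a cohort as PNG pairs + fiducial JSON + a CSV manifest.

    Returns the manifest with columns ``patient_id, pre_path, post_path,
    fiducial_path, label_1..label_12`` and writes it to ``cohort.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        pre_path = out / f"{rec.patient_id}_pre.png"
        post_path = out / f"{rec.patient_id}_post.png"
        fid_path = out / f"{rec.patient_id}_fiducials.json"
        Image.fromarray(rec.pre).save(pre_path)
        Image.fromarray(rec.post).save(post_path)
        fid_path.write_text(rec.fiducials.to_json())
        row = {
            "patient_id": rec.patient_id,
            "pre_path": str(pre_path),
            "post_path": str(post_path),
            "fiducial_path": str(fid_path),
        }
        for k in range(1, 13):
            row[f"label_{k}"] = rec.truth.sector_labels[k].value
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "cohort.csv", index=False)
    return manifest
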