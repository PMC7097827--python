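"""Diagnostic agreement statistics and the clock-annulus visualization.

Screening performance is summarized against the histopathology gold
standard with 2x2 confusion matrices, sensitivity / specificity / accuracy,
and Cohen's chance-corrected kappa.  Because published reader studies print
rates rather than raw counts, ``confusion_from_rates`` reconstructs integer
matrices from printed sensitivity/specificity and the known class sizes, and
``pool_confusions`` combines readers by cellwise summation.  Patient-level
calls use the rule that one VIA-positive clock sector makes the patient
positive.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw
from scipy import stats

from .synthetic import VIA_NEG, VIA_POS, Grade

__all__ = [
    "ConfusionMatrix",
    "AgreementReport",
    "KappaResult",
    "confusion_from_rates",
    "binary_metrics",
    "cohen_kappa",
    "pool_confusions",
    "aggregate_patient",
    "agreement_rate",
    "render_annulus",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts: rows = truth (positive, negative), cols = prediction."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class AgreementReport:
    """Percent metrics plus kappa; NaN marks undefined ratios."""

    sensitivity: float
    specificity: float
    accuracy: float
    kappa: float = float("nan")
    p_value: float = float("nan")


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    se0: float
    z: float
    p_value: float


def confusion_from_rates(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> ConfusionMatrix:
    """Reconstruct integer 2x2 counts from printed percent rates.

    ``tp = round(sens/100 * n_pos)`` and ``tn = round(spec/100 * n_neg)``;
    a warning is raised when the printed rate is not consistent with an
    integer count to within rounding slack.
    """
    if not (0 <= sensitivity <= 100 and 0 <= specificity <= 100):
        raise ValueError("rates must lie in [0, 100]")
    if n_pos < 0 or n_neg < 0:
        raise ValueError("class counts must be non-negative")
    tp_f = sensitivity / 100.0 * n_pos
    tn_f = specificity / 100.0 * n_neg
    tp, tn = int(round(tp_f)), int(round(tn_f))
    for name, val, cnt in (("sensitivity", tp_f, tp), ("specificity", tn_f, tn)):
        if abs(val - cnt) > 0.05:
            warnings.warn(
                f"{name} not consistent with an integer count "
                f"({val:.3f} rounded to {cnt})",
                stacklevel=2,
            )
    return ConfusionMatrix(tp=tp, fn=n_pos - tp, fp=n_neg - tn, tn=tn)


def binary_metrics(cm: ConfusionMatrix) -> AgreementReport:
    """Sensitivity, specificity and accuracy in percent (NaN if undefined)."""
    sens = 100.0 * cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn > 0 else float("nan")
    spec = 100.0 * cm.tn / (cm.fp + cm.tn) if cm.fp + cm.tn > 0 else float("nan")
    acc = 100.0 * (cm.tp + cm.tn) / cm.total
    return AgreementReport(sensitivity=sens, specificity=spec, accuracy=acc)


def cohen_kappa(cm: ConfusionMatrix, method: str = "asymptotic") -> KappaResult:
    """Cohen's kappa with a two-sided test of kappa != 0.

    kappa = (p_o - p_e) / (1 - p_e) with the usual marginal-product chance
    agreement.  Significance uses the large-sample (Fleiss) standard error
    under the null by default; ``method="exact"`` performs the exact
    conditional (hypergeometric, fixed-margins) test, practical for n <= 30.
    """
    n = cm.total
    if n < 2:
        raise ValueError("kappa requires at least two cases")
    po = (cm.tp + cm.tn) / n
    row_pos = (cm.tp + cm.fn) / n  # truth-positive marginal
    col_pos = (cm.tp + cm.fp) / n  # predicted-positive marginal
    pe = row_pos * col_pos + (1 - row_pos) * (1 - col_pos)
    if pe >= 1.0:
        return KappaResult(float("nan"), float("nan"), float("nan"), float("nan"))
    kappa = (po - pe) / (1 - pe)

    if method == "exact":
        p = _exact_kappa_pvalue(cm, kappa)
        return KappaResult(kappa, float("nan"), float("nan"), p)
    if method != "asymptotic":
        raise ValueError("method must be 'asymptotic' or 'exact'")

    margins = ((row_pos, col_pos), (1 - row_pos, 1 - col_pos))
    s = sum(a * b * (a + b) for a, b in margins)
    var0 = pe + pe**2 - s
    se0 = math.sqrt(max(var0, 0.0)) / ((1 - pe) * math.sqrt(n))
    if se0 == 0:
        return KappaResult(kappa, 0.0, float("inf"), 0.0)
    z = kappa / se0
    p = 2.0 * stats.norm.sf(abs(z))
    return KappaResult(kappa, se0, z, p)


def _exact_kappa_pvalue(cm: ConfusionMatrix, kappa_obs: float) -> float:
    """Exact two-sided p for kappa under fixed margins (hypergeometric tp)."""
    n = cm.total
    a = cm.tp + cm.fn  # truth positives
    b = cm.tp + cm.fp  # predicted positives
    lo = max(0, a + b - n)
    hi = min(a, b)
    pe = (a * b + (n - a) * (n - b)) / n**2
    p = 0.0
    for t in range(lo, hi + 1):
        po = (t + (n - a - b + t)) / n
        k = (po - pe) / (1 - pe)
        if abs(k) >= abs(kappa_obs) - 1e-12:
            p += stats.hypergeom.pmf(t, n, a, b)
    return min(p, 1.0)


def pool_confusions(matrices) -> ConfusionMatrix:
    """Cellwise sum of confusion matrices (e.g. pooling several readers)."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("need at least one confusion matrix")
    return ConfusionMatrix(
        tp=sum(m.tp for m in matrices),
        fn=sum(m.fn for m in matrices),
        fp=sum(m.fp for m in matrices),
        tn=sum(m.tn for m in matrices),
    )


def aggregate_patient(slice_predictions) -> str:
    """Patient-level call: positive iff >= 1 of the 12 sectors is VIA_POS.

    ``slice_predictions`` is a mapping sector -> label or a sequence of 12
    labels; missing sectors are treated as negative (logged).
    """
    if hasattr(slice_predictions, "items"):
        labels = dict(slice_predictions)
    else:
        labels = {i + 1: v for i, v in enumerate(slice_predictions)}
    missing = set(range(1, 13)) - set(labels)
    if missing:
        log.warning("sectors %s missing; treated as negative", sorted(missing))
    return VIA_POS if any(v == VIA_POS for v in labels.values()) else VIA_NEG


def agreement_rate(pred_a, pred_b) -> float:
    """Percent of common sectors on which two raters give the same label."""
    common = set(pred_a) & set(pred_b)
    if not common:
        raise ValueError("no overlapping sectors between the two ratings")
    hits = sum(pred_a[k] == pred_b[k] for k in common)
    return 100.0 * hits / len(common)


# ---------------------------------------------------------------------------
# clock-annulus rendering

_PRED_COLORS = {VIA_POS: (220, 40, 40), VIA_NEG: (50, 80, 220)}
_GRADE_COLORS = {
    Grade.CIN2PLUS: (220, 40, 40),
    Grade.CIN1: (40, 180, 60),
    Grade.NORMAL: (50, 80, 220),
}
_MARGIN = 60


def render_annulus(
    post_image: np.ndarray,
    center: tuple[float, float],
    slice_predictions: dict[int, str],
    truth_grades: dict[int, Grade] | None = None,
    roi_radius: float | None = None,
) -> np.ndarray:
    """Draw the per-clock-position prediction annulus around a cervicogram.

    Red annulus segments mark predicted VIA+, blue VIA-; inner tick lines
    show the gold-standard grade (red CIN2+, green CIN1, blue normal); a
    yellow outer mark flags sectors where a VIA+ prediction matches a CIN2+
    truth.  Output is the input image padded by a fixed margin; rendering is
    fully deterministic.
    """
    h, w = post_image.shape[:2]
    if roi_radius is None:
        roi_radius = 0.45 * min(h, w)
    r_in = 1.05 * roi_radius
    r_out = r_in + 18
    canvas = Image.new("RGB", (w + 2 * _MARGIN, h + 2 * _MARGIN), (0, 0, 0))
    canvas.paste(Image.fromarray(np.asarray(post_image, dtype=np.uint8)), (_MARGIN, _MARGIN))
    draw = ImageDraw.Draw(canvas)
    cx, cy = center[0] + _MARGIN, center[1] + _MARGIN

    def box(r):
        return (cx - r, cy - r, cx + r, cy + r)

    for k in range(1, 13):
        # clock angle (deg from 12 o'clock, clockwise) -> PIL angle (from +x)
        start = 30 * k - 15 - 90
        end = 30 * k + 15 - 90
        pred = slice_predictions.get(k, VIA_NEG)
        draw.arc(box((r_in + r_out) / 2), start, end, fill=_PRED_COLORS[pred], width=int(r_out - r_in))
        if truth_grades is not None and k in truth_grades:
            grade = Grade(truth_grades[k])
            mid = math.radians(30 * k - 90)
            x0 = cx + (r_in - 14) * math.cos(mid)
            y0 = cy + (r_in - 14) * math.sin(mid)
            x1 = cx + (r_in - 2) * math.cos(mid)
            y1 = cy + (r_in - 2) * math.sin(mid)
            draw.line((x0, y0, x1, y1), fill=_GRADE_COLORS[grade], width=3)
            if pred == VIA_POS and grade is Grade.CIN2PLUS:
                draw.arc(box(r_out + 5), start, end, fill=(250, 220, 40), width=4)
    return np.asarray(canvas)
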