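"""Segmentation-quality metrics and the study's statistical procedures.

Pixel-overlap metrics (MCC, Dice, Jaccard), a one-directional mean surface
distance, PSNR, a two-way random-effects single-rater ICC(2,1) with its
F-based 95 % confidence interval, a one-way ANOVA built from the classical
mean-squares decomposition, and the relative-improvement arithmetic used to
summarize filter gains.

Conventions for degenerate inputs are explicit: MCC returns 0 whenever a
denominator factor vanishes; Dice of two empty masks is 1; the mean surface
distance of an empty prediction is an error (undefined, flagged rather than
silently imputed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage, stats

from .types import as_array


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-wise 2x2 contingency counts (foreground = positive)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(pred, truth) -> ConfusionCounts:
    """Count TP/TN/FP/FN between two binary masks of identical shape."""
    p = np.asarray(as_array(pred), dtype=bool)
    t = np.asarray(as_array(truth), dtype=bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    tn = int(np.count_nonzero(~p & ~t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    return ConfusionCounts(tp, tn, fp, fn)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    tp, tn, fp, fn = float(c.tp), float(c.tn), float(c.fp), float(c.fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def dsc(c: ConfusionCounts) -> float:
    """Dice score 2TP/(2TP+FP+FN); two empty masks score 1 by convention."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2.0 * c.tp / denom


def jc(dsc_value: float) -> float:
    """Jaccard coefficient from Dice: DSC / (2 - DSC) (== intersection/union)."""
    if not 0.0 <= dsc_value <= 1.0:
        raise ValueError("dsc_value must lie in [0, 1]")
    return dsc_value / (2.0 - dsc_value)


def msd(
    pred, truth, pixel_spacing_mm: float | None = None, symmetric: bool = False
) -> float:
    """Mean surface distance (one-directional by default).

    Mean over predicted-foreground pixels of the Euclidean distance to the
    nearest truth-foreground pixel. ``symmetric=True`` instead averages the
    two directed boundary-to-boundary distances (the usual surface-based
    variant). In pixels, or mm when ``pixel_spacing_mm`` is given.
    """
    p = np.asarray(as_array(pred), dtype=bool)
    t = np.asarray(as_array(truth), dtype=bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if not t.any():
        raise ValueError("truth mask has no foreground; MSD undefined")
    if not p.any():
        raise ValueError("empty prediction; MSD undefined (flagged, not imputed)")
    scale = 1.0 if pixel_spacing_mm is None else float(pixel_spacing_mm)
    if symmetric:
        pb, tb = _boundary(p), _boundary(t)
        d_pt = ndimage.distance_transform_edt(~tb)[pb]
        d_tp = ndimage.distance_transform_edt(~pb)[tb]
        return scale * float((d_pt.sum() + d_tp.sum()) / (d_pt.size + d_tp.size))
    dist_to_truth = ndimage.distance_transform_edt(~t)
    return scale * float(dist_to_truth[p].mean())


def _boundary(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return mask & ~eroded


def psnr(mse: float, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio 10*log10(peak^2 / mse), in dB."""
    if mse < 0:
        raise ValueError("mse must be >= 0")
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(peak * peak / mse)


@dataclass(frozen=True)
class MetricReport:
    """Per-image metric rows for one pipeline arm."""

    arm: str
    mcc: list[float]
    dsc: list[float]
    jc: list[float]
    msd: list[float]

    def means(self) -> dict[str, float]:
        out = {
            "mcc": float(np.mean(self.mcc)),
            "dsc": float(np.mean(self.dsc)),
            "jc": float(np.mean(self.jc)),
        }
        finite = [v for v in self.msd if math.isfinite(v)]
        out["msd"] = float(np.mean(finite)) if finite else math.nan
        return out


def evaluate_masks(pred_masks, truth_masks, arm: str = "") -> MetricReport:
    """Score a list of predicted masks against their ground truths.

    Slices with an empty prediction get MSD = NaN (excluded from the mean)
    rather than aborting the whole report.
    """
    rows = {"mcc": [], "dsc": [], "jc": [], "msd": []}
    for p, t in zip(pred_masks, truth_masks):
        c = confusion_counts(p, t)
        d = dsc(c)
        rows["mcc"].append(mcc(c))
        rows["dsc"].append(d)
        rows["jc"].append(jc(d))
        try:
            rows["msd"].append(msd(p, t))
        except ValueError:
            rows["msd"].append(math.nan)
    return MetricReport(arm=arm, **rows)


# ---------------------------------------------------------------------------
# inter-rater reliability and group comparison
# ---------------------------------------------------------------------------


def icc_2_1(ratings: np.ndarray, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is an (n subjects) x (k raters) matrix with no missing cells.
    Returns the point estimate and the F-based (1 - alpha) confidence
    interval from the standard mean-squares decomposition.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x raters matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total == 0:
        raise ValueError("zero total variance; ICC undefined")

    msr = ss_rows / (n - 1)          # between-subjects
    msc = ss_cols / (k - 1)          # between-raters
    mse = ss_err / ((n - 1) * (k - 1))

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if mse == 0.0:
        # perfect agreement: no residual variance, the interval degenerates
        return float(icc), (float(icc), float(icc))

    # F-based interval (McGraw & Wong 1996)
    fj = msc / mse
    a = k * icc / (n * (1.0 - icc)) if icc < 1 else math.inf
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1 else math.inf
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_star = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_lower = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_star * mse) / (
        f_star * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_lower * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_lower * msr
    )
    return float(icc), (float(lower), float(upper))


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, tuple[int, int], float]:
    """Classical one-way ANOVA from the between/within mean squares.

    Returns ``(F, (df_between, df_within), p)``. When both mean squares are
    zero (all values identical) F is defined as 0 with p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two values")
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = len(arrays) - 1
    df_w = n_total - len(arrays)
    msb = ssb / df_b
    msw = ssw / df_w
    if msw == 0.0:
        if msb == 0.0:
            return 0.0, (df_b, df_w), 1.0
        return math.inf, (df_b, df_w), 0.0
    f = msb / msw
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), (df_b, df_w), p


ImprovementMode = Literal["relative_to_before", "relative_to_after", "difference"]


def relative_improvement(before: float, after: float, mode: ImprovementMode) -> float:
    """Percent improvement between two metric values.

    ``relative_to_before``: (after - before) / before * 100 — for metrics
    where larger is better. ``relative_to_after``: (before - after) / after *
    100 — for distances, where improvement means a decrease. ``difference``:
    after - before, in percentage points.
    """
    if mode == "relative_to_before":
        if before == 0:
            raise ValueError("zero denominator (before)")
        return (after - before) / before * 100.0
    if mode == "relative_to_after":
        if after == 0:
            raise ValueError("zero denominator (after)")
        return (before - after) / after * 100.0
    if mode == "difference":
        return after - before
    raise ValueError(f"unknown mode {mode!r}")
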