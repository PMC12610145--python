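"""Hough-circle diameter measurement and three-tier aneurysm severity grading.

An aneurysm cross-section in a segmentation mask is detected with a full
three-dimensional Hough accumulator over (center_row, center_col, radius):
every edge pixel votes for all centers at each candidate radius, and peaks
are local maxima of the accumulator. The detected radius (optionally refined
to sub-pixel precision) is converted to a diameter in millimetres and graded
against the clinical thresholds:

    low risk      D < 30 mm
    moderate risk 30 mm <= D <= 55 mm
    high risk     D > 55 mm

Patient severity is taken from the maximum slice diameter (the clinical
convention for aneurysm size). The 3x3 confusion matrix is oriented with
rows = predicted class and columns = true class; per-class sensitivity is
diagonal / column sum, precision is diagonal / row sum, and the per-class
accuracy column equals the sensitivity column — macro values are unweighted
means over the three classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, signal
from sklearn.base import BaseEstimator

from .types import as_array

SEVERITY_CLASSES = ("low", "moderate", "high")


@dataclass(frozen=True)
class DetectedCircle:
    """A Hough detection: center (px), radius (px) and accumulator votes."""

    center_row: float
    center_col: float
    radius: float
    votes: int

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


def edge_map(mask_or_map, threshold: float = 0.5) -> np.ndarray:
    """Foreground pixels with at least one background 4-neighbor.

    Probability maps are binarized at ``threshold`` first. An empty
    foreground yields an empty edge map (not an error).
    """
    arr = np.asarray(as_array(mask_or_map), dtype=float)
    fg = arr >= threshold
    padded = np.pad(fg, 1, mode="constant", constant_values=False)
    has_bg_neighbor = ~(
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return (fg & has_bg_neighbor).astype(np.uint8)


def _ring_template(radius: int) -> np.ndarray:
    """Offsets (dy, dx) with Euclidean length in [radius - 1.5, radius + 0.5].

    Edge pixels of a rasterized disk of true radius r lie up to one pixel
    inside the boundary, and the accumulator quantizes the center to the
    pixel grid (up to 0.5 px off in each axis), so this annulus is the
    support needed to collect the full perimeter at the best grid center. A
    zero-width ring would split the votes between adjacent radius bins and
    neighboring centers.
    """
    r = int(radius)
    ax = np.arange(-r - 1, r + 2)
    dist = np.hypot(ax[:, None], ax[None, :])
    return ((dist >= r - 1.5) & (dist <= r + 0.5)).astype(float)


def hough_accumulator(
    edges: np.ndarray, radius_range: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Full 3-D vote array over (radius, center_row, center_col).

    Each edge pixel votes for every center whose rounded distance equals the
    candidate radius. Returns ``(radii, votes)`` with ``votes`` of shape
    ``(len(radii), H, W)`` and integer counts.
    """
    e = np.asarray(as_array(edges), dtype=float)
    rmin, rmax = int(radius_range[0]), int(radius_range[1])
    if rmin < 1:
        raise ValueError("rmin must be >= 1")
    if rmax < rmin:
        raise ValueError("rmax must be >= rmin")
    if rmax >= max(e.shape) / 2 + 1:
        raise ValueError("rmax must be smaller than half the image size")
    radii = np.arange(rmin, rmax + 1)
    votes = np.empty((radii.size, *e.shape), dtype=np.int64)
    for i, r in enumerate(radii):
        conv = signal.fftconvolve(e, _ring_template(r), mode="same")
        votes[i] = np.rint(conv).astype(np.int64)
    return radii, votes


def hough_circles(
    edges,
    radius_range: tuple[int, int],
    min_votes: int | None = None,
    min_votes_fraction: float = 0.6,
    max_circles: int | None = None,
) -> list[DetectedCircle]:
    """Detect circles as accumulator peaks, strongest first.

    ``min_votes`` is an absolute vote floor; when ``None`` each radius uses
    ``min_votes_fraction`` of its ideal circumference ``2*pi*r``. Peaks are
    3-D local maxima; near-duplicate peaks (same circle seen at neighboring
    cells) are suppressed. Ties break deterministically toward the smaller
    radius, then row-major center order.
    """
    e = np.asarray(as_array(edges))
    if not e.any():
        return []
    radii, votes = hough_accumulator(e, radius_range)
    if min_votes is None:
        floors = np.ceil(min_votes_fraction * 2.0 * np.pi * radii).astype(np.int64)
    else:
        floors = np.full(radii.size, int(min_votes), dtype=np.int64)

    is_max = votes >= ndimage.maximum_filter(votes, size=3, mode="constant")
    above = votes >= floors[:, None, None]
    cand = np.argwhere(is_max & above)
    if cand.size == 0:
        return []
    cand_votes = votes[cand[:, 0], cand[:, 1], cand[:, 2]]
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], -cand_votes))
    accepted: list[DetectedCircle] = []
    for idx in order:
        ri, cy, cx = cand[idx]
        r = int(radii[ri])
        dup = False
        for acc in accepted:
            tol = max(2.0, 0.25 * acc.radius)
            if (
                abs(acc.center_row - cy) <= tol
                and abs(acc.center_col - cx) <= tol
                and abs(acc.radius - r) <= tol
            ):
                dup = True
                break
        if not dup:
            accepted.append(DetectedCircle(float(cy), float(cx), float(r), int(cand_votes[idx])))
            if max_circles is not None and len(accepted) >= max_circles:
                break
    return accepted


def refine_circle(circle: DetectedCircle, edges, n_iter: int = 2) -> DetectedCircle:
    """Sub-pixel refinement of a Hough peak against the edge pixels.

    The accumulator quantizes centers and radii to the pixel grid, which
    quantizes diameters to 2-px steps. Refinement re-centers the circle on
    the centroid of the edge pixels within ±1.5 px of the detected ring and
    sets the radius to their mean distance plus a 0.5 px rasterization
    offset (edge-pixel centers of a rasterized disk of radius r lie in
    (r - 1, r], i.e. ~0.5 px inside the true boundary on average).
    """
    ys, xs = np.nonzero(np.asarray(as_array(edges)))
    if ys.size == 0:
        return circle
    cy, cx, r = circle.center_row, circle.center_col, circle.radius
    for _ in range(n_iter):
        dist = np.hypot(ys - cy, xs - cx)
        sel = np.abs(dist - r) <= 1.5
        if not sel.any():
            return circle
        cy = float(ys[sel].mean())
        cx = float(xs[sel].mean())
        r = float(np.hypot(ys[sel] - cy, xs[sel] - cx).mean()) + 0.5
    return DetectedCircle(cy, cx, r, circle.votes)


def measure_diameter_mm(circle: DetectedCircle, pixel_spacing_mm: float) -> float:
    """Circle diameter in millimetres: 2 * radius * spacing."""
    if not pixel_spacing_mm > 0:
        raise ValueError("pixel spacing must be positive")
    return 2.0 * circle.radius * pixel_spacing_mm


def classify_severity(diameter_mm: float) -> str:
    """Three-tier grade; 30 mm and 55 mm both belong to the moderate tier."""
    if not diameter_mm > 0:
        raise ValueError("diameter must be positive")
    if diameter_mm < 30.0:
        return "low"
    if diameter_mm <= 55.0:
        return "moderate"
    return "high"


def patient_severity(slice_diameters: Sequence[float]) -> tuple[float, str]:
    """Patient diameter = maximum over slices; grade from the thresholds."""
    diameters = [d for d in slice_diameters if d is not None and np.isfinite(d)]
    if not diameters:
        raise ValueError("no valid slice diameter; patient unclassifiable")
    d = float(max(diameters))
    return d, classify_severity(d)


def confusion_matrix3(pred: Sequence[str], truth: Sequence[str]) -> np.ndarray:
    """3x3 counts, rows = predicted class, columns = true class."""
    if len(pred) != len(truth):
        raise ValueError("pred and truth must have equal length")
    index = {c: i for i, c in enumerate(SEVERITY_CLASSES)}
    cm = np.zeros((3, 3), dtype=np.int64)
    for p, t in zip(pred, truth):
        cm[index[p], index[t]] += 1
    return cm


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class and macro sensitivity / precision / accuracy, in percent."""

    sensitivity: tuple[float, float, float]
    precision: tuple[float, float, float]
    accuracy: tuple[float, float, float]
    macro_sensitivity: float
    macro_precision: float
    macro_accuracy: float


def class_metrics(cm: np.ndarray) -> ClassMetrics:
    """Table-style per-class metrics from a rows=predicted 3x3 matrix.

    Sensitivity_i = cm[i, i] / column_i sum; precision_i = cm[i, i] / row_i
    sum; the accuracy column repeats the sensitivity column (the table
    convention this mirrors). Classes with an empty column (sensitivity) or
    row (precision) are excluded from the macro mean with a warning.
    """
    cm = np.asarray(cm, dtype=np.int64)
    if cm.shape != (3, 3):
        raise ValueError("expected a 3x3 matrix")
    if (cm < 0).any():
        raise ValueError("counts must be nonnegative")
    if cm.sum() == 0:
        raise ValueError("all-zero confusion matrix")
    col = cm.sum(axis=0)
    row = cm.sum(axis=1)
    diag = np.diag(cm)

    sens, prec = [], []
    for i in range(3):
        sens.append(100.0 * diag[i] / col[i] if col[i] > 0 else np.nan)
        prec.append(100.0 * diag[i] / row[i] if row[i] > 0 else np.nan)
    sens_arr, prec_arr = np.array(sens), np.array(prec)
    if np.isnan(sens_arr).any() or np.isnan(prec_arr).any():
        warnings.warn("classes with empty rows/columns excluded from macro means")
    return ClassMetrics(
        sensitivity=tuple(sens),
        precision=tuple(prec),
        accuracy=tuple(sens),
        macro_sensitivity=float(np.nanmean(sens_arr)),
        macro_precision=float(np.nanmean(prec_arr)),
        macro_accuracy=float(np.nanmean(sens_arr)),
    )


class HoughSeverityClassifier(BaseEstimator):
    """Slice-mask to severity-grade estimator (rule-based, no training).

    Parameters
    ----------
    pixel_spacing_mm : float
        Millimetres per pixel of the input masks.
    threshold : float
        Binarization threshold applied to probability maps.
    diameter_range_mm : (float, float)
        Clinical search range; sets the Hough radius range.
    min_votes_fraction : float
        Vote floor as a fraction of the ideal circumference.
    refine : bool
        Apply sub-pixel circle refinement before measuring.

    ``predict(X)`` maps an (n, H, W) stack of masks/probability maps to a
    list of severity labels; ``measure(X)`` returns the diameters (mm),
    with NaN where no circle is found.
    """

    def __init__(
        self,
        pixel_spacing_mm: float = 1.5,
        threshold: float = 0.5,
        diameter_range_mm: tuple[float, float] = (15.0, 70.0),
        min_votes_fraction: float = 0.6,
        refine: bool = True,
    ):
        self.pixel_spacing_mm = pixel_spacing_mm
        self.threshold = threshold
        self.diameter_range_mm = diameter_range_mm
        self.min_votes_fraction = min_votes_fraction
        self.refine = refine

    def fit(self, X=None, y=None):
        if not self.pixel_spacing_mm > 0:
            raise ValueError("pixel_spacing_mm must be positive")
        lo, hi = self.diameter_range_mm
        self.radius_range_ = (
            max(1, int(np.floor(lo / 2.0 / self.pixel_spacing_mm))),
            int(np.ceil(hi / 2.0 / self.pixel_spacing_mm)) + 1,
        )
        return self

    def measure_one(self, mask_or_map) -> float:
        """Diameter (mm) of the strongest circle in one slice, NaN if none."""
        if not hasattr(self, "radius_range_"):
            self.fit()
        edges = edge_map(mask_or_map, self.threshold)
        found = hough_circles(
            edges,
            self.radius_range_,
            min_votes_fraction=self.min_votes_fraction,
            max_circles=1,
        )
        if not found:
            return float("nan")
        best = refine_circle(found[0], edges) if self.refine else found[0]
        return measure_diameter_mm(best, self.pixel_spacing_mm)

    def measure(self, X) -> np.ndarray:
        arr = np.asarray(as_array(X), dtype=float)
        stack = arr[None] if arr.ndim == 2 else arr
        return np.array([self.measure_one(a) for a in stack])

    def predict(self, X) -> list[str]:
        return [
            classify_severity(d) if np.isfinite(d) else "unclassifiable"
            for d in self.measure(X)
        ]
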