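"""Four-filter denoising bank: average, median, Wiener, median-modified Wiener.

All four filters share sliding-window machinery with symmetric (reflect)
border padding. The Wiener filter is the classical local-statistics form

    out = mu_L + (sigma_L^2 - sigma_n^2) / sigma_L^2 * (I - mu_L),

and the median-modified Wiener filter (MMWF) replaces the local mean mu_L by
the local median m_L, combining median edge preservation with Wiener-style
adaptive shrinkage. The gain is clamped to [0, 1] (standard practice; an
unclamped negative gain would invert local contrast where sigma_L^2 <
sigma_n^2). The noise variance sigma_n^2, when not given, is estimated as
the mean of the per-pixel local variances — the classical sliding-window
Wiener convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .types import Image2D, as_array

#: variance floor preventing division by zero on perfectly flat windows
VAR_EPS = 1e-12

FilterKind = Literal["average", "median", "wiener", "mmwf"]


def _check_window(window) -> tuple[int, int]:
    if np.isscalar(window):
        window = (int(window), int(window))
    h, w = int(window[0]), int(window[1])
    if h < 1 or w < 1 or h % 2 == 0 or w % 2 == 0:
        raise ValueError(f"window dimensions must be odd and >= 1, got {(h, w)}")
    return h, w


@dataclass(frozen=True)
class FilterSpec:
    """Filter kind, odd window geometry, kernel weights and sigma_n^2."""

    kind: FilterKind
    window: tuple[int, int] = (3, 3)
    kernel: np.ndarray | None = None
    noise_variance: float | str = "estimate"

    def __post_init__(self) -> None:
        object.__setattr__(self, "window", _check_window(self.window))
        if self.kind not in ("average", "median", "wiener", "mmwf"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.kernel is not None:
            k = np.asarray(self.kernel, dtype=float)
            if k.shape != self.window:
                raise ValueError("kernel shape must match window")
            if (k < 0).any() or not np.isclose(k.sum(), 1.0, atol=1e-8):
                raise ValueError("kernel weights must be nonnegative and sum to 1")
            object.__setattr__(self, "kernel", k)
        if not isinstance(self.noise_variance, str) and self.noise_variance < 0:
            raise ValueError("noise_variance must be >= 0")


@dataclass(frozen=True)
class LocalStats:
    """Per-pixel local mean, median and (population) variance over the window."""

    mean: np.ndarray
    median: np.ndarray
    variance: np.ndarray


def local_stats(image, window=(3, 3)) -> LocalStats:
    """Sliding-window mean / median / population variance, reflect padding."""
    h, w = _check_window(window)
    arr = np.asarray(as_array(image), dtype=float)
    if h > arr.shape[0] * 2 or w > arr.shape[1] * 2:
        raise ValueError("window larger than the reflect-padded image")
    # center on the global mean first: exact zeros on constant images and
    # better conditioning of the E[x^2] - E[x]^2 subtraction
    c = arr.mean()
    d = arr - c
    mean_d = ndimage.uniform_filter(d, size=(h, w), mode="reflect")
    sq_mean = ndimage.uniform_filter(d * d, size=(h, w), mode="reflect")
    variance = np.maximum(sq_mean - mean_d * mean_d, 0.0)
    median = ndimage.median_filter(arr, size=(h, w), mode="reflect")
    return LocalStats(mean=mean_d + c, median=median, variance=variance)


def estimate_noise_variance(image, window=(3, 3)) -> float:
    """Mean of the per-pixel local variances (classical Wiener estimate).

    Biased low by a factor (m-1)/m for an m-pixel window on pure i.i.d.
    noise, and biased high across structure edges; adequate for the uniform
    global sigma_n^2 the filter bank needs.
    """
    arr = as_array(image)
    h, w = _check_window(window)
    if arr.shape[0] <= h or arr.shape[1] <= w:
        raise ValueError("image must be larger than the window")
    return float(local_stats(arr, (h, w)).variance.mean())


def wiener_shrink(values, center_stat, local_variance, noise_variance) -> np.ndarray:
    """Core Wiener/MMWF update: center + clamped gain * (I - center).

    ``center_stat`` is the local mean (Wiener) or local median (MMWF); the
    gain (sigma_L^2 - sigma_n^2)/sigma_L^2 is clamped to [0, 1].
    """
    values = np.asarray(values, dtype=float)
    center = np.asarray(center_stat, dtype=float)
    var = np.asarray(local_variance, dtype=float)
    gain = np.clip((var - noise_variance) / np.maximum(var, VAR_EPS), 0.0, 1.0)
    return center + gain * (values - center)


class _WindowedFilter(TransformerMixin, BaseEstimator):
    """Shared sklearn plumbing: accepts (H, W) or (n, H, W), stateless fit."""

    kind: FilterKind = "average"

    def __init__(self, window=(3, 3)):
        self.window = window

    def fit(self, X=None, y=None):
        _check_window(self.window)
        return self

    def _filter_one(self, arr: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def transform(self, X) -> np.ndarray:
        self.fit(X)
        arr = np.asarray(as_array(X), dtype=float)
        if arr.ndim == 2:
            return self._filter_one(arr)
        if arr.ndim == 3:
            return np.stack([self._filter_one(a) for a in arr])
        raise ValueError(f"expected (H, W) or (n, H, W), got shape {arr.shape}")


class AverageFilter(_WindowedFilter):
    """Normalized linear smoothing kernel (uniform by default)."""

    kind = "average"

    def __init__(self, window=(3, 3), kernel=None):
        super().__init__(window)
        self.kernel = kernel

    def _filter_one(self, arr: np.ndarray) -> np.ndarray:
        h, w = _check_window(self.window)
        if self.kernel is None:
            kernel = np.full((h, w), 1.0 / (h * w))
        else:
            kernel = np.asarray(self.kernel, dtype=float)
            if kernel.shape != (h, w):
                raise ValueError("kernel shape must match window")
            if (kernel < 0).any() or not np.isclose(kernel.sum(), 1.0, atol=1e-8):
                raise ValueError("kernel must be nonnegative and sum to 1")
        return ndimage.convolve(arr, kernel, mode="reflect")


class MedianFilter(_WindowedFilter):
    kind = "median"

    def _filter_one(self, arr: np.ndarray) -> np.ndarray:
        h, w = _check_window(self.window)
        return ndimage.median_filter(arr, size=(h, w), mode="reflect")


class WienerFilter(_WindowedFilter):
    """Classical local-statistics Wiener filter.

    ``noise_variance='estimate'`` estimates sigma_n^2 from the data during
    ``fit`` (stored as ``noise_variance_``); a float bypasses the estimator.
    """

    kind = "wiener"
    _center = "mean"

    def __init__(self, window=(3, 3), noise_variance: float | str = "estimate"):
        super().__init__(window)
        self.noise_variance = noise_variance

    def fit(self, X=None, y=None):
        _check_window(self.window)
        if isinstance(self.noise_variance, str):
            if self.noise_variance != "estimate":
                raise ValueError("noise_variance must be a float or 'estimate'")
            if X is None:
                raise ValueError("noise_variance='estimate' requires data in fit")
            arr = np.asarray(as_array(X), dtype=float)
            stack = arr[None] if arr.ndim == 2 else arr
            self.noise_variance_ = float(
                np.mean([estimate_noise_variance(a, self.window) for a in stack])
            )
        else:
            if self.noise_variance < 0:
                raise ValueError("noise_variance must be >= 0")
            self.noise_variance_ = float(self.noise_variance)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "noise_variance_"):
            self.fit(X)
        arr = np.asarray(as_array(X), dtype=float)
        if arr.ndim == 2:
            return self._filter_one(arr)
        return np.stack([self._filter_one(a) for a in arr])

    def _filter_one(self, arr: np.ndarray) -> np.ndarray:
        stats = local_stats(arr, self.window)
        center = stats.mean if self._center == "mean" else stats.median
        out = wiener_shrink(arr, center, stats.variance, self.noise_variance_)
        return np.clip(out, 0.0, 1.0) if arr.min() >= 0 and arr.max() <= 1 else out


class MedianModifiedWienerFilter(WienerFilter):
    """Wiener shrinkage anchored at the local median instead of the mean."""

    kind = "mmwf"
    _center = "median"


_FILTER_CLASSES = {
    "average": AverageFilter,
    "median": MedianFilter,
    "wiener": WienerFilter,
    "mmwf": MedianModifiedWienerFilter,
}


def make_filter(spec: FilterSpec):
    """Instantiate the estimator matching a :class:`FilterSpec`."""
    if spec.kind == "average":
        return AverageFilter(spec.window, spec.kernel)
    if spec.kind == "median":
        return MedianFilter(spec.window)
    cls = _FILTER_CLASSES[spec.kind]
    return cls(spec.window, spec.noise_variance)


def _apply(image, spec: FilterSpec, expected_kind: str):
    if spec.kind != expected_kind:
        raise ValueError(f"spec.kind is {spec.kind!r}, expected {expected_kind!r}")
    out = make_filter(spec).fit(as_array(image)).transform(as_array(image))
    if isinstance(image, Image2D):
        return image.with_values(out)
    return out


def apply_average(image, spec: FilterSpec):
    return _apply(image, spec, "average")


def apply_median(image, spec: FilterSpec):
    return _apply(image, spec, "median")


def apply_wiener(image, spec: FilterSpec):
    return _apply(image, spec, "wiener")


def apply_mmwf(image, spec: FilterSpec):
    return _apply(image, spec, "mmwf")
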