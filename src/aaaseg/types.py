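"""Light-weight containers shared across the pipeline.

Images are plain ``numpy`` arrays wherever possible; :class:`Image2D` adds
the spatial metadata (pixel spacing, patient / slice identity) that the
phantom generator, the manifest writer and the severity classifier need.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np


def _as_float_image(values: np.ndarray) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError("image contains non-finite values")
    return arr


@dataclass(frozen=True)
class Image2D:
    """A 2-D grayscale slice with spatial metadata.

    Parameters
    ----------
    values : ndarray of shape (H, W)
        Intensities, finite reals (normally in [0, 1]).
    pixel_spacing_mm : float
        In-plane pixel size in millimetres per pixel (> 0).
    patient_id : str
        Opaque patient identifier.
    slice_index : int
        Position of the slice along the scan axis (>= 0).
    """

    values: np.ndarray
    pixel_spacing_mm: float = 1.0
    patient_id: str = ""
    slice_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _as_float_image(self.values))
        if not self.pixel_spacing_mm > 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if self.slice_index < 0:
            raise ValueError("slice_index must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray) -> "Image2D":
        """Return a copy carrying the same metadata but new pixel data."""
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class BinaryMask:
    """A {0, 1} segmentation mask sharing the grid of its image."""

    values: np.ndarray
    pixel_spacing_mm: float = 1.0
    patient_id: str = ""
    slice_index: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise ValueError(f"expected a 2-D mask, got shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.isin(uniq, [0, 1]).all():
            raise ValueError("mask values must be exactly {0, 1}")
        object.__setattr__(self, "values", arr.astype(np.uint8))
        if not self.pixel_spacing_mm > 0:
            raise ValueError("pixel_spacing_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def foreground_count(self) -> int:
        return int(self.values.sum())


def as_array(image) -> np.ndarray:
    """Accept an :class:`Image2D`, :class:`BinaryMask` or bare array."""
    if isinstance(image, (Image2D, BinaryMask)):
        return image.values
    return np.asarray(image)
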