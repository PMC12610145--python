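"""Synthetic vessel-phantom cohorts.

The clinical CT cohort this pipeline was designed around (35 patients,
80–140 axial slices each, a bright quasi-circular aneurysm cross-section on
a soft-tissue background) is not publicly available, so every stage of the
pipeline is exercised on phantoms with the same statistical structure:

* a filled, optionally slightly elliptical vessel of known diameter
  (15–70 mm) rendered as a bright plateau on a textured background,
* a hard {0, 1} ground-truth mask (no anti-aliasing, so overlap metrics are
  exact) while the image-side plateau edge is anti-aliased,
* per-slice diameter jitter (±2 %) that never crosses a severity class
  boundary, with patient severity defined by the maximum slice diameter,
* 1–3 dimmer "organ" blobs whose intensity stays at least 0.1 below the
  vessel plateau, so an intensity-threshold segmentation oracle exists,
* per-class diameter bands that keep a 2 mm guard away from the 30 mm and
  55 mm severity thresholds, making 100 % end-to-end classification on
  clean masks a legitimate target.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

from .types import BinaryMask, Image2D

#: diameter bands (mm) used when drawing per-class patient diameters; each
#: band stays >= 2 mm clear of the 30 / 55 mm severity thresholds.
CLASS_BANDS: dict[str, tuple[float, float]] = {
    "low": (18.0, 28.0),
    "moderate": (32.0, 53.0),
    "high": (57.0, 70.0),
}

CLASS_ORDER = ("low", "moderate", "high")

#: brightness of the vessel plateau above the background level.
PLATEAU_CONTRAST = 0.25


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single synthetic patient.

    Attributes
    ----------
    image_size : int
        Pixels per side of the square slice.
    pixel_spacing_mm : float
        Millimetres per pixel (> 0). The clinical spacing is not public;
        1.5 mm/px is a realistic abdominal-CT stand-in.
    vessel_diameter_mm : float
        True aneurysm diameter (major axis), 15–70 mm.
    ellipticity : float
        Minor/major axis ratio in [0.8, 1.0]; 1.0 renders a circle.
    background_level : float
        Mean soft-tissue intensity in (0, 1).
    texture_sd : float
        Standard deviation of the Gaussian background texture (>= 0).
    n_slices : int
        Slices per patient.
    organ_blobs : (int, int)
        Inclusive range for the number of dimmer distractor blobs.
    diameter_jitter : float
        Per-slice fractional diameter jitter (anatomical variation along
        the vessel); the jittered diameter never crosses a severity
        threshold.
    seed : int
        RNG seed; slices are deterministic given (seed, slice_index).
    """

    image_size: int = 256
    pixel_spacing_mm: float = 1.5
    vessel_diameter_mm: float = 40.0
    ellipticity: float = 1.0
    background_level: float = 0.45
    texture_sd: float = 0.02
    n_slices: int = 100
    organ_blobs: tuple[int, int] = (1, 3)
    diameter_jitter: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 8:
            raise ValueError("image_size too small")
        if not self.pixel_spacing_mm > 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if not 0.8 <= self.ellipticity <= 1.0:
            raise ValueError("ellipticity must lie in [0.8, 1.0]")
        if not 0 < self.background_level < 1:
            raise ValueError("background_level must lie in (0, 1)")
        if self.texture_sd < 0:
            raise ValueError("texture_sd must be >= 0")
        if self.vessel_diameter_mm / self.pixel_spacing_mm >= self.image_size:
            raise ValueError(
                f"vessel of {self.vessel_diameter_mm} mm at "
                f"{self.pixel_spacing_mm} mm/px does not fit in a "
                f"{self.image_size}-px field of view"
            )
        if self.organ_blobs[0] < 0 or self.organ_blobs[1] < self.organ_blobs[0]:
            raise ValueError("organ_blobs must be a nonnegative (lo, hi) range")
        if not 0 <= self.diameter_jitter < 0.2:
            raise ValueError("diameter_jitter must lie in [0, 0.2)")

    @property
    def plateau_level(self) -> float:
        return min(self.background_level + PLATEAU_CONTRAST, 1.0)


def severity_band_of(diameter_mm: float) -> str:
    """Severity class implied by a diameter (low / moderate / high)."""
    if diameter_mm < 30.0:
        return "low"
    if diameter_mm <= 55.0:
        return "moderate"
    return "high"


def _class_preserving_clip(diameter_mm: float, nominal_mm: float) -> float:
    """Clip a jittered diameter so its severity class matches the nominal one."""
    cls = severity_band_of(nominal_mm)
    if cls == "low":
        return min(diameter_mm, 30.0 - 1e-6)
    if cls == "moderate":
        return float(np.clip(diameter_mm, 30.0, 55.0))
    return max(diameter_mm, 55.0 + 1e-6)


def _ellipse_grids(
    size: int, center: tuple[float, float], a: float, b: float, vertical: bool
) -> np.ndarray:
    """Normalized elliptic distance rho of every pixel center (rho <= 1 inside)."""
    rows = np.arange(size)[:, None] - center[0]
    cols = np.arange(size)[None, :] - center[1]
    if vertical:
        rows, cols = cols, rows
    return np.sqrt((cols / a) ** 2 + (rows / b) ** 2)


def generate_slice(
    spec: PhantomSpec, slice_index: int, rng: np.random.Generator | None = None
) -> tuple[Image2D, BinaryMask, float]:
    """Render one slice and its ground-truth mask.

    Returns ``(image, mask, true_diameter_mm)`` where the diameter carries the
    per-slice ±2 % jitter (clipped so the severity class never changes). The
    mask is a hard binary ellipse whose major-axis chord equals
    ``round(diameter / spacing)`` pixels exactly; the image-side plateau edge
    is anti-aliased over roughly one pixel.

    Deterministic given ``spec.seed`` and ``slice_index``; an explicit ``rng``
    overrides the derived one.
    """
    if slice_index < 0 or slice_index >= spec.n_slices:
        raise ValueError(f"slice_index {slice_index} outside [0, {spec.n_slices})")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([int(spec.seed) % (2**31), int(slice_index)])
        )

    size = spec.image_size
    j = spec.diameter_jitter
    jitter = rng.uniform(-j, j) if j > 0 else 0.0
    diameter_mm = _class_preserving_clip(
        spec.vessel_diameter_mm * (1.0 + jitter), spec.vessel_diameter_mm
    )

    d_px = int(round(diameter_mm / spec.pixel_spacing_mm))
    if d_px >= size:
        raise ValueError("jittered vessel exceeds the field of view")

    # even chord -> half-integer center; odd chord -> integer center, so the
    # major-axis chord through the center is exactly d_px pixels.
    margin = d_px // 2 + 2
    lo, hi = margin, size - margin
    cr = int(rng.integers(lo, hi))
    cc = int(rng.integers(lo, hi))
    if d_px % 2 == 0:
        center = (cr + 0.5, cc + 0.5)
    else:
        center = (float(cr), float(cc))
    vertical = bool(rng.integers(0, 2))
    a = d_px / 2.0
    b = spec.ellipticity * a

    rho = _ellipse_grids(size, center, a, b, vertical)
    mask = (rho <= 1.0).astype(np.uint8)

    image = np.full((size, size), spec.background_level, dtype=float)
    if spec.texture_sd > 0:
        image += rng.normal(0.0, spec.texture_sd, size=(size, size))

    # dimmer distractor blobs, capped 0.1 below the plateau
    n_blobs = int(rng.integers(spec.organ_blobs[0], spec.organ_blobs[1] + 1))
    blob_cap = spec.plateau_level - 0.1
    for _ in range(n_blobs):
        br = float(rng.uniform(size * 0.1, size * 0.9))
        bc = float(rng.uniform(size * 0.1, size * 0.9))
        ba = float(rng.uniform(3.0, size * 0.12))
        bb = ba * float(rng.uniform(0.6, 1.0))
        lo_level = min(spec.background_level + 0.05, blob_cap)
        level = float(rng.uniform(lo_level, blob_cap))
        brho = _ellipse_grids(size, (br, bc), ba, bb, False)
        balpha = np.clip((1.0 - brho) * ba + 0.5, 0.0, 1.0)
        image = image * (1.0 - balpha) + level * balpha

    # vessel plateau, anti-aliased on the inner rim only so the image
    # foreground coincides exactly with the hard binary mask
    alpha = np.clip((1.0 - rho) * a + 0.5, 0.0, 1.0) * mask
    image = image * (1.0 - alpha) + spec.plateau_level * alpha
    image = np.clip(image, 0.0, 1.0)

    pid = f"P{spec.seed:05d}"
    img = Image2D(image, spec.pixel_spacing_mm, pid, slice_index)
    msk = BinaryMask(mask, spec.pixel_spacing_mm, pid, slice_index)
    return img, msk, float(diameter_mm)


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic patient: a spec plus its drawn diameter and class."""

    patient_id: str
    spec: PhantomSpec
    true_diameter_mm: float
    true_class: str

    def slices(self) -> Iterator[tuple[Image2D, BinaryMask, float]]:
        """Yield (image, mask, slice_diameter_mm) for every slice."""
        for k in range(self.spec.n_slices):
            img, msk, d = generate_slice(self.spec, k)
            yield (
                replace(img, patient_id=self.patient_id),
                replace(msk, patient_id=self.patient_id),
                d,
            )


def draw_class_diameter(cls: str, rng: np.random.Generator) -> float:
    """Draw a patient diameter uniformly within its guard-banded class band."""
    lo, hi = CLASS_BANDS[cls]
    return float(rng.uniform(lo, hi))


def generate_cohort(
    n_patients: int,
    severity_mix: tuple[int, int, int] = (4, 12, 19),
    slices_per_patient_range: tuple[int, int] = (80, 140),
    master_seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> list[PatientRecord]:
    """Build a reproducible cohort of phantom patients.

    ``severity_mix`` is ``(n_low, n_moderate, n_high)``; the default matches
    a 35-patient cohort with 4 low-, 12 moderate- and 19 high-risk patients.
    Each patient's diameter is drawn uniformly inside its class band and all
    slices of a patient share the patient id and (nominal) diameter.
    """
    if any(n < 0 for n in severity_mix):
        raise ValueError("severity_mix counts must be nonnegative")
    if sum(severity_mix) != n_patients:
        raise ValueError(
            f"severity_mix {severity_mix} does not sum to n_patients={n_patients}"
        )
    lo_s, hi_s = slices_per_patient_range
    if lo_s < 1 or hi_s < lo_s:
        raise ValueError("invalid slices_per_patient_range")
    if base_spec is None:
        base_spec = PhantomSpec()

    rng = np.random.default_rng(int(master_seed) % (2**31))
    records: list[PatientRecord] = []
    idx = 0
    for cls, count in zip(CLASS_ORDER, severity_mix):
        for _ in range(count):
            diameter = draw_class_diameter(cls, rng)
            n_slices = int(rng.integers(lo_s, hi_s + 1))
            seed = int(rng.integers(0, 2**31 - 1))
            spec = replace(
                base_spec,
                vessel_diameter_mm=diameter,
                n_slices=n_slices,
                seed=seed,
            )
            records.append(
                PatientRecord(
                    patient_id=f"pt{idx:03d}",
                    spec=spec,
                    true_diameter_mm=diameter,
                    true_class=cls,
                )
            )
            idx += 1
    return records


def write_cohort(
    records: Sequence[PatientRecord], out_dir: str | Path, image_format: str = "tiff"
) -> Path:
    """Write slices, masks and a CSV manifest under ``out_dir``.

    Slices go out as 16-bit grayscale TIFF (or PNG), masks as 8-bit PNG with
    foreground 255. Returns the manifest path.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "patient_id",
                "slice_index",
                "image_file",
                "mask_file",
                "pixel_spacing_mm",
                "slice_diameter_mm",
                "true_diameter_mm",
                "true_class",
            ]
        )
        for rec in records:
            for img, msk, d in rec.slices():
                stem = f"{rec.patient_id}_s{img.slice_index:04d}"
                data16 = np.round(img.values * 65535).astype(np.uint16)
                if image_format == "tiff":
                    img_name = f"images/{stem}.tiff"
                    tifffile.imwrite(out / img_name, data16)
                else:
                    img_name = f"images/{stem}.png"
                    iio.imwrite(out / img_name, data16)
                mask_name = f"masks/{stem}.png"
                iio.imwrite(out / mask_name, (msk.values * 255).astype(np.uint8))
                writer.writerow(
                    [
                        rec.patient_id,
                        img.slice_index,
                        img_name,
                        mask_name,
                        f"{img.pixel_spacing_mm:g}",
                        f"{d:.4f}",
                        f"{rec.true_diameter_mm:.4f}",
                        rec.true_class,
                    ]
                )
    return manifest
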