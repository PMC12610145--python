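"""End-to-end experiment orchestration.

Runs the full chain phantom -> noise -> filter arm -> U-Net -> metrics ->
severity classification as a paired design: every arm sees byte-identical
noisy inputs (one noise realization per cohort), the same patient-wise
split, and its own network trained on that arm's filtered images. The
report is a pydantic model, so its JSON schema is published programmatically
(:func:`report_json_schema`) and any report can be validated by parsing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from pydantic import BaseModel
from skimage.transform import resize as _sk_resize

from . import filters as flt
from . import metrics as mx
from . import severity as sev
from . import unet as un
from .noise import PoissonGaussianNoise, RoiSpec, calibrate_gamma, measure_snr_db
from .phantom import PhantomSpec, generate_cohort
from .types import BinaryMask, Image2D, as_array

ARMS = ("noisy", "average", "median", "wiener", "mmwf")


def resize_bicubic(image, target_size: int | tuple[int, int]):
    """Bicubic resize; pixel spacing is rescaled by the size ratio.

    Accepts an :class:`Image2D` (metadata preserved, spacing rescaled) or a
    bare array. Values are clipped back to [0, 1]; resizing to the current
    size returns the data unchanged.
    """
    if np.isscalar(target_size):
        target = (int(target_size), int(target_size))
    else:
        target = (int(target_size[0]), int(target_size[1]))
    if target[0] < 1 or target[1] < 1:
        raise ValueError("target size must be positive")
    arr = np.asarray(as_array(image), dtype=float)
    if arr.shape == target:
        out = arr.copy()
    else:
        down = target[0] < arr.shape[0] or target[1] < arr.shape[1]
        out = _sk_resize(arr, target, order=3, mode="reflect", anti_aliasing=down)
        out = np.clip(out, 0.0, 1.0)
    if isinstance(image, Image2D):
        ratio = arr.shape[0] / target[0]
        return Image2D(
            out,
            image.pixel_spacing_mm * ratio,
            image.patient_id,
            image.slice_index,
        )
    return out


def stack_masks_to_volume(masks: Sequence) -> np.ndarray:
    """Stack per-slice binary masks into a (z, y, x) binary volume."""
    if len(masks) == 0:
        raise ValueError("no masks to stack")
    arrays = [np.asarray(as_array(m), dtype=np.uint8) for m in masks]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("all masks must share the same shape")
    return np.stack(arrays, axis=0)


def make_filter_arm(name: str, window=(3, 3), noise_variance="estimate"):
    """Instantiate the denoiser for an arm name; 'noisy' means no filtering."""
    if name == "noisy":
        return None
    if name == "average":
        return flt.AverageFilter(window)
    if name == "median":
        return flt.MedianFilter(window)
    if name == "wiener":
        return flt.WienerFilter(window, noise_variance)
    if name == "mmwf":
        return flt.MedianModifiedWienerFilter(window, noise_variance)
    raise ValueError(f"unknown arm {name!r}")


# ---------------------------------------------------------------------------
# report schema
# ---------------------------------------------------------------------------


class NoiseReport(BaseModel):
    gamma: float
    rho: float
    target_snr_db: float
    measured_snr_db: float
    clipped_fraction: float


class ArmReport(BaseModel):
    name: str
    metric_means: dict[str, float]
    per_slice_dsc: list[float]
    confusion_matrix: list[list[int]]
    macro_sensitivity: float
    macro_precision: float
    macro_accuracy: float
    classification_accuracy: float
    final_train_loss: float


class AnovaReport(BaseModel):
    metric: str
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


class ExperimentReport(BaseModel):
    master_seed: int
    n_patients: int
    severity_mix: tuple[int, int, int]
    image_size: int
    pixel_spacing_mm: float
    noise: NoiseReport
    arms: list[ArmReport]
    anova: list[AnovaReport]


def report_json_schema() -> dict:
    """The published JSON schema of the experiment report."""
    return ExperimentReport.model_json_schema()


def validate_report(data: dict) -> ExperimentReport:
    """Parse (and thereby validate) a report against the schema."""
    return ExperimentReport.model_validate(data)


# ---------------------------------------------------------------------------
# experiment
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Configuration of one paired multi-arm experiment.

    Defaults are smoke-scale (micro network, small cohort) so that a full
    run finishes in minutes on one CPU; scale up via the fields.
    """

    n_patients: int = 6
    severity_mix: tuple[int, int, int] = (1, 2, 3)
    slices_per_patient: tuple[int, int] = (4, 6)
    image_size: int = 48
    pixel_spacing_mm: float = 2.0
    rho: float = 0.05
    target_snr_db: float = 13.0
    arms: tuple[str, ...] = ("noisy", "mmwf")
    filter_window: tuple[int, int] = (3, 3)
    unet_channels: tuple[int, ...] = (4, 8, 16)
    unet_epochs: int = 30
    learning_rate: float = 2e-3
    batch_size: int = 3
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    threshold: float = 0.5
    master_seed: int = 0
    oracle_masks: bool = False  # skip the network, classify ground truth

    def phantom_spec(self) -> PhantomSpec:
        # small fields of view need a smaller vessel ceiling
        return PhantomSpec(
            image_size=self.image_size, pixel_spacing_mm=self.pixel_spacing_mm
        )


def _cohort_diameter_ceiling(image_size: int, spacing: float) -> float:
    """Largest class-band diameter that fits the field of view with margin."""
    return (image_size - 8) * spacing


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Execute every arm of the paired design and assemble the report."""
    # --- cohort and shared noise realization ------------------------------
    spacing = config.pixel_spacing_mm
    base = PhantomSpec(image_size=config.image_size, pixel_spacing_mm=spacing)
    if 70.0 >= _cohort_diameter_ceiling(config.image_size, spacing):
        raise ValueError(
            "field of view too small for the 15-70 mm diameter bands; "
            "increase image_size or pixel_spacing_mm"
        )
    cohort = generate_cohort(
        config.n_patients,
        config.severity_mix,
        config.slices_per_patient,
        master_seed=config.master_seed,
        base_spec=base,
    )
    slices: list[tuple[str, Image2D, BinaryMask]] = []
    for rec in cohort:
        for img, msk, _d in rec.slices():
            slices.append((rec.patient_id, img, msk))
    clean = np.stack([s[1].values for s in slices])
    truth = np.stack([s[2].values for s in slices])
    patient_ids = [s[0] for s in slices]

    gamma = calibrate_gamma(base.background_level, config.rho, config.target_snr_db)
    noiser = PoissonGaussianNoise(
        gamma=gamma, rho=config.rho, seed=config.master_seed + 1
    )
    noisy = noiser.transform(clean)
    roi = RoiSpec(1, 1, max(4, config.image_size // 8), max(4, config.image_size // 8))
    snr = measure_snr_db(noisy[0], roi)
    noise_report = NoiseReport(
        gamma=gamma,
        rho=config.rho,
        target_snr_db=config.target_snr_db,
        measured_snr_db=snr,
        clipped_fraction=noiser.clipped_fraction_,
    )

    train_recs, val_recs, test_recs = un.split_by_patient(
        cohort, config.split_fractions, seed=config.master_seed + 2
    )
    subset_of = {}
    for rec in train_recs:
        subset_of[rec.patient_id] = "train"
    for rec in val_recs:
        subset_of[rec.patient_id] = "val"
    for rec in test_recs:
        subset_of[rec.patient_id] = "test"
    idx_train = [i for i, p in enumerate(patient_ids) if subset_of[p] == "train"]
    idx_val = [i for i, p in enumerate(patient_ids) if subset_of[p] == "val"]
    idx_test = [i for i, p in enumerate(patient_ids) if subset_of[p] == "test"]
    # segmentation metrics are scored on held-out patients only
    idx_eval = idx_test if idx_test else list(range(len(patient_ids)))

    truth_class = {rec.patient_id: rec.true_class for rec in cohort}
    classifier = sev.HoughSeverityClassifier(
        pixel_spacing_mm=spacing, threshold=config.threshold
    ).fit()

    per_arm_dsc: dict[str, list[float]] = {}
    arm_reports: list[ArmReport] = []
    for arm in config.arms:
        denoiser = make_filter_arm(arm, config.filter_window)
        if denoiser is None:
            arm_images = noisy
        else:
            arm_images = denoiser.fit(noisy).transform(noisy)

        if config.oracle_masks:
            pred_masks = truth.copy()
            final_loss = 0.0
        else:
            seg = un.UNetSegmenter(
                input_size=config.image_size,
                encoder_channels=config.unet_channels,
                learning_rate=config.learning_rate,
                epochs=config.unet_epochs,
                batch_size=config.batch_size,
                seed=config.master_seed + 3,
                threshold=config.threshold,
            )
            seg.fit(
                arm_images[idx_train],
                truth[idx_train],
                validation_data=(arm_images[idx_val], truth[idx_val])
                if idx_val
                else None,
            )
            pred_masks = seg.predict_masks(arm_images)
            final_loss = float(seg.history_["train_loss"].iloc[-1])

        report = mx.evaluate_masks(
            pred_masks[idx_eval], truth[idx_eval], arm=arm
        )
        per_arm_dsc[arm] = report.dsc

        # per-patient severity from the maximum slice diameter
        pred_class, true_class_list = [], []
        for rec in cohort:
            rows = [i for i, p in enumerate(patient_ids) if p == rec.patient_id]
            diam = [classifier.measure_one(pred_masks[i]) for i in rows]
            diam = [d for d in diam if math.isfinite(d)]
            if diam:
                _, cls = sev.patient_severity(diam)
            else:
                cls = "unclassifiable"
            pred_class.append(cls)
            true_class_list.append(truth_class[rec.patient_id])
        usable = [i for i, c in enumerate(pred_class) if c != "unclassifiable"]
        cm = sev.confusion_matrix3(
            [pred_class[i] for i in usable], [true_class_list[i] for i in usable]
        )
        accuracy = (
            100.0
            * sum(p == t for p, t in zip(pred_class, true_class_list))
            / len(pred_class)
        )
        cmx = sev.class_metrics(cm) if cm.sum() else None
        arm_reports.append(
            ArmReport(
                name=arm,
                metric_means=report.means(),
                per_slice_dsc=[float(v) for v in report.dsc],
                confusion_matrix=cm.tolist(),
                macro_sensitivity=cmx.macro_sensitivity if cmx else float("nan"),
                macro_precision=cmx.macro_precision if cmx else float("nan"),
                macro_accuracy=cmx.macro_accuracy if cmx else float("nan"),
                classification_accuracy=accuracy,
                final_train_loss=final_loss,
            )
        )

    anova_reports = []
    if len(config.arms) >= 2:
        f, (dfb, dfw), p = mx.one_way_anova(
            [per_arm_dsc[a] for a in config.arms]
        )
        anova_reports.append(
            AnovaReport(
                metric="dsc", f_statistic=f, df_between=dfb, df_within=dfw, p_value=p
            )
        )

    return ExperimentReport(
        master_seed=config.master_seed,
        n_patients=config.n_patients,
        severity_mix=config.severity_mix,
        image_size=config.image_size,
        pixel_spacing_mm=spacing,
        noise=noise_report,
        arms=arm_reports,
        anova=anova_reports,
    )
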