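# aaaseg

Noise-robust segmentation and severity grading of abdominal aortic
aneurysms (AAA) on axial CT slices.

An AAA is a localized widening of the abdominal aorta; it is diagnosed when
the vessel diameter `D` exceeds 30 mm and usually operated above 55 mm, so
automated grading reduces to measuring `D` on a reliable segmentation:

* **low risk** `D < 30 mm` — **moderate** `30 ≤ D ≤ 55 mm` — **high**
  `D > 55 mm`.

CT noise obscures the vessel boundary and degrades learned segmentation.
This package implements, end to end, a pipeline for studying how classical
denoising before segmentation affects downstream grading:

1. **Noise injection** — signal-dependent Poisson–Gaussian model
   `I = R + sqrt(γR + ρ²)·δ`, with `γ` calibrated so a soft-tissue region
   of interest lands at a target SNR (default 13 dB, `ρ = 0.05`);
2. **Filter bank** — average, median, Wiener
   `μ_L + (σ_L²−σ_n²)/σ_L² (I−μ_L)` and the median-modified Wiener filter
   (MMWF), the same shrinkage anchored at the local median `m_L`;
3. **U-Net segmentation** — symmetric encoder–decoder (3×3 conv + batch
   norm + ReLU blocks, 2×2 pooling / up-convolution, skip connections,
   sigmoid head), trained with MSE loss and Adam under a strict
   patient-wise train/validation/test split; implemented in pure NumPy so
   it runs anywhere, reproducibly, on one CPU;
4. **Severity grading** — Hough circle transform on the segmented mask
   (full 3-D accumulator with sub-pixel refinement), diameter in mm,
   three-tier grade, and the per-class/macro sensitivity–precision–accuracy
   analytics of a 3×3 confusion matrix (rows = predicted, columns = true);
5. **Metrics & statistics** — Matthews correlation, Dice, Jaccard, mean
   surface distance, PSNR, one-way ANOVA across filter arms and ICC(2,1)
   inter-rater reliability.

Because the clinical cohort such studies use is not public, a **phantom
module** generates synthetic patients (bright quasi-circular vessel of
known diameter on textured soft tissue, 80–140 slices per patient, severity
mix 4/12/19 low/moderate/high by default) with hard binary ground-truth
masks — every claim the test suite makes is verified against these
phantoms. See `docs/methods.md` for the full model description and design
choices.

## Worked example

```python
import numpy as np
from aaaseg import (
    PhantomSpec, generate_slice, NoiseParams, add_poisson_gaussian,
    calibrate_gamma, MedianModifiedWienerFilter, HoughSeverityClassifier,
    confusion_counts, dsc,
)

spec = PhantomSpec(image_size=64, pixel_spacing_mm=1.5, vessel_diameter_mm=40.0, seed=7)
image, mask, true_d = generate_slice(spec, 0)

gamma = calibrate_gamma(spec.background_level, rho=0.05, target_snr_db=13.0)
noisy = add_poisson_gaussian(image.values, NoiseParams(gamma, 0.05, seed=1))

denoised = MedianModifiedWienerFilter().fit(noisy).transform(noisy)

clf = HoughSeverityClassifier(pixel_spacing_mm=1.5).fit()
d_mm = clf.measure_one(mask.values)
print(f"gamma = {gamma:.4f}")
print(f"true diameter = {true_d:.1f} mm, measured = {d_mm:.1f} mm")
print(f"grade: {clf.predict(mask.values[None])[0]}")
print(f"threshold-oracle Dice on clean slice: "
      f"{dsc(confusion_counts(image.values > 0.55, mask.values)):.3f}")
```

prints

```
gamma = 0.0170
true diameter = 40.2 mm, measured = 40.8 mm
grade: moderate
threshold-oracle Dice on clean slice: 0.990
```

i.e. the calibrated Poisson coefficient for 0.45-intensity tissue at 13 dB,
a Hough diameter within a millimetre of the rendered truth (hence the
*moderate* grade for a ~40 mm aneurysm), and confirmation that clean
phantoms are essentially threshold-separable (Dice 0.99 — the anti-aliased
plateau rim accounts for the remainder) — the oracle the U-Net is measured
against.

A full paired experiment (noisy arm vs the four filter arms, shared noise
realization and split, one network per arm) is one call:

```python
from aaaseg import ExperimentConfig, run_experiment
report = run_experiment(ExperimentConfig(arms=("noisy", "mmwf"), master_seed=0))
print({a.name: round(a.metric_means["dsc"], 3) for a in report.arms})
```

There is also a CLI: `aaaseg phantom | noise | denoise | evaluate |
classify | run` (see `aaaseg --help`).

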