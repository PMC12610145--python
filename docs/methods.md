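# Methods

`aaaseg` models an end-to-end pipeline for grading abdominal aortic
aneurysms (AAA) from axial CT slices under degraded image quality: noise is
injected into clean slices, removed again by one of four classical filters,
the vessel is segmented by a U-Net, and the aneurysm diameter measured on
the segmentation drives a three-tier clinical severity grade. Because the
clinical cohort this design targets is not publicly available, the package
ships a phantom generator that reproduces the cohort's statistical
structure, so every stage is testable end to end.

## Noise model

CT noise is modeled as the Gaussian approximation of a mixed
Poisson–Gaussian process,

    I = R + eta(R) * delta,    eta^2(R) = gamma * R + rho^2,

with `R` the clean image on a normalized [0, 1] intensity scale, `delta`
i.i.d. standard normal, `gamma >= 0` the signal-dependent (quantum)
coefficient and `rho >= 0` the constant electronic-noise standard
deviation. Defaults: `rho = 0.05`; `gamma` is calibrated so that a
homogeneous soft-tissue region of interest lands at a target SNR of 13 dB,

    sigma_target = background / 10^(SNR/20),
    gamma = (sigma_target^2 - rho^2) / background.

SNR uses the amplitude convention `20 * log10(mean/sd)`; this is the only
convention under which adding `rho = 0.05` noise to tissue of intensity
~0.5 produces a drop from the low-20s dB to ~13 dB. Noised images are
clipped back to [0, 1] by default (the filters and the network assume that
range); the clipped fraction is recorded. The model is spatially white — it
does not reproduce the correlated, nonstationary noise of real CT
reconstruction, which is a stated limitation of this design generally.

## Filter bank

All four denoisers share a sliding window (default 3×3, the smallest
standard choice; no reference value exists for the original experiment) with
symmetric (reflect) border padding:

* **average** — convolution with a nonnegative kernel summing to 1
  (uniform by default);
* **median** — per-pixel window median;
* **Wiener** — the classical local-statistics form
  `out = mu_L + (sigma_L^2 - sigma_n^2)/sigma_L^2 * (I - mu_L)`;
* **MMWF** (median-modified Wiener) — the same update anchored at the local
  median `m_L` instead of the mean.

Numerical choices: the shrinkage gain is clamped to [0, 1] (a negative gain
where `sigma_L^2 < sigma_n^2` would invert local contrast); a `1e-12`
variance floor guards flat windows; with `sigma_n^2 = 0` both Wiener
variants reduce exactly to the identity. The noise variance, when not
supplied, is the mean of the per-pixel local variances — the classical
sliding-window convention; on pure i.i.d. noise this underestimates the
true variance by (m−1)/m for an m-pixel window and overestimates across
structure edges. Local variances are computed after centering on the global
mean, so constant images yield exactly zero.

## U-Net

The segmentation network is the standard symmetric encoder–decoder: per
level two 3×3 convolutions with batch normalization and ReLU; 2×2 max
pooling down, 2×2 transposed-convolution up with skip concatenation; a
final 1×1 convolution and sigmoid produces a per-pixel probability map in
[0, 1]. Channel widths double per level. Training minimizes mean squared
error against the binary mask with Adam, no data augmentation; per-epoch
loss and PSNR are recorded, and with peak 1 the identity
`PSNR = 10*log10(1/MSE)` holds at every epoch. Probability maps are
binarized at 0.5 (configurable; the midpoint is the symmetric default).

The full-scale protocol (`full_config`) is a 256-px input, channels
64→1024, 200 epochs, batch 3, learning rate 5e-4. Two reduced presets make
CPU runs practical: `desk_config` (64-px input, channels 8→128, ≤50 epochs,
trains in about a minute per run on one core) and `micro_config` (32-px,
three levels) for smoke tests. The network is implemented directly in
NumPy — forward and backward passes are hand-vectorized (shift-and-sum
convolutions, explicit batch-norm and pooling gradients) — which keeps the
package dependency-light, CPU-only and bit-reproducible for a given seed;
the backward pass is verified against float64 finite differences in the
development suite. Splitting is patient-wise: all slices of a patient land
in exactly one of train/validation/test, eliminating identity leakage
between subsets.

## Segmentation metrics and statistics

Per slice, from pixel confusion counts (foreground = vessel): Matthews
correlation coefficient, Dice `2TP/(2TP+FP+FN)`, Jaccard `DSC/(2−DSC)`
(identically `TP/(TP+FP+FN)`), and a mean surface distance defined
one-directionally as the mean distance from predicted-foreground pixels to
the nearest truth-foreground pixel (a symmetric boundary-based variant is
available behind a flag). Degenerate conventions are explicit: MCC is 0
when a denominator factor vanishes; Dice of two empty masks is 1; the
surface distance of an empty prediction is an error, flagged rather than
imputed (the batch evaluator records NaN and excludes it from means).

Group differences between filter arms use a one-way ANOVA built from the
classical between/within mean squares, with the p-value from the F survival
function; inter-rater reliability uses ICC(2,1) — two-way random effects,
absolute agreement, single rater — with the standard F-based confidence
interval. Improvement summaries are percentages relative to the baseline
value for overlap metrics and relative to the improved value for distances
(where improvement means a decrease), or plain percentage-point
differences.

## Diameter measurement and severity grading

Segmented masks are reduced to edge maps (foreground pixels with a
background 4-neighbor) and fed to a full three-dimensional Hough
accumulator over (center row, center column, radius): each edge pixel votes
for every center whose distance lies in `[r − 1.5, r + 0.5]` — the support
of a rasterized circle's inner boundary allowing for the ±0.5 px center
quantization of the grid. Peaks are 3-D local maxima above a vote floor of
60 % of the ideal circumference `2*pi*r`; ties break deterministically
(smaller radius, then row-major center) and near-duplicate peaks are
suppressed. Because the accumulator quantizes diameters to 2-px steps
(3 mm at the default spacing), the detected circle is refined before
measurement: the center moves to the centroid of edge pixels within ±1.5 px
of the ring and the radius becomes their mean distance plus a 0.5 px
rasterization offset (edge-pixel centers of a rasterized disk of radius r
lie in (r − 1, r]). On clean phantom masks this brings the diameter error
under 1 mm.

The diameter is `2 * radius * pixel_spacing_mm`; the patient diameter is
the maximum over slices (the clinical convention for aneurysm size); grades
are low (< 30 mm), moderate (30–55 mm inclusive) and high (> 55 mm).
Confusion matrices are oriented rows = predicted, columns = true;
per-class sensitivity is diagonal/column-sum, precision diagonal/row-sum,
and the per-class "accuracy" column repeats sensitivity (the convention of
the published severity table this mirrors); macro values are unweighted
means over the three classes, excluding classes with an empty row or
column with a warning.

## Phantom generator

Each slice is a bright vessel cross-section on a textured soft-tissue
background:

* field: 256×256 px default at 1.5 mm/px (no reference spacing exists for
  the original data; 1.5 mm/px is a realistic abdominal-CT stand-in);
* background 0.45 with Gaussian texture (sd 0.02) and 1–3 dimmer "organ"
  blobs capped 0.1 below the vessel plateau, so a threshold oracle always
  exists;
* vessel: filled ellipse (axis ratio 0.8–1.0, default a circle) whose
  major-axis chord is exactly `round(diameter/spacing)` pixels — even
  chords center on half-pixel positions, odd chords on pixel centers; the
  mask is hard binary while the image-side plateau edge is anti-aliased
  over ~1 px inside the mask; plateau = background + 0.25;
* per-slice diameter jitter of ±2 %, clipped so the severity class never
  changes; patient severity is defined by the maximum slice diameter.

Cohorts draw patient diameters uniformly within guard-banded class bands —
low [18, 28] mm, moderate [32, 53] mm, high [57, 70] mm — each at least
2 mm clear of the 30/55 mm thresholds, so 100 % end-to-end classification
on clean masks is a legitimate expectation rather than a coin flip at the
boundaries. Default cohort mix: 4 low / 12 moderate / 19 high of 35
patients, 80–140 slices each. Everything is reproducible from a master
seed, and slices are deterministic given (patient seed, slice index).

What the phantoms do not emulate: anatomical shape variability (fusiform or
saccular aneurysms, adjacent vessels), partial-volume effects, contrast
inhomogeneity, and spatially correlated reconstruction noise. Passing tests
therefore demonstrate the correctness of the pipeline's mechanics and its
qualitative behavior under signal-dependent noise, not clinical-grade
performance.

## Experiment orchestration and problem sizes

`run_experiment` executes a paired design: one cohort, one noise
realization, one patient-wise split shared by every arm; each arm filters
the same noisy images (the `noisy` arm skips filtering), trains its own
network on its own filtered training slices, and is scored on the held-out
test patients. Segmentation metrics, the per-patient severity confusion
matrix and a one-way ANOVA across arms on per-slice Dice are assembled into
a pydantic report whose JSON schema is published programmatically;
validation is by parsing.

Default problem sizes are chosen so that the full suite and the acceptance
script run in minutes on a single CPU core: smoke experiments use 48-px
slices at 2 mm/px with a three-level network; the quantitative comparisons
(network Dice on clean phantoms, filtered-vs-noisy ordering) run at the
desk scale — 64-px slices at 1.5 mm/px, the five-level 8→128-channel
network, 8–10 patients with 5–7 slices each, 15–20 epochs. At this scale
each filtered arm reproduces the qualitative result that denoising before
segmentation improves held-out Dice relative to training on raw noisy
inputs; absolute metric values are not comparable to full-scale clinical
results and are not asserted.

## Known limitations

* The one-directional surface distance follows its stated definition
  literally (mean over predicted-foreground pixels); surface-based
  summaries in the literature often use the symmetric boundary variant,
  which is provided but off by default.
* The Hough detector assumes near-circular cross-sections; strongly
  elliptical or irregular aneurysms bias the diameter low (the generator's
  ellipticity knob exposes this failure mode deliberately).
* Training the full 256-px, 64→1024-channel protocol in NumPy on one CPU
  is possible but slow; the reduced presets exist precisely so the
  pipeline's claims are tested at tractable scale.
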