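# Methods

## The problem

Snapshot multispectral imaging (MSI) cameras capture a full spectral
data cube in one exposure by tiling the sensor with a repeating 4×4
mosaic of 16 interference filters. The filters have broad, overlapping
and sensor-specific passbands, which makes a physics-first inversion
(calibrated sensor model + photon transport) laborious and fragile.
`oxymosaic` implements the alternative: learn the mapping from the
camera's own 16-channel spectra to skin hemoglobin oxygen saturation
(SO2, %) directly, using a validated point-measuring diffuse-reflectance
probe as the regression target, with data collected during arterial and
venous occlusion provocations so the targets span nearly the whole
0–100% range.

Because no in vivo recordings are deposited, the package ships a
synthetic occlusion-cohort simulator that exercises every stage of the
pipeline end to end; all quantitative results produced here are
simulation analogs.

## Preprocessing (module `mosaic`)

Raw frames are dark-corrected (negatives clamped to zero — intensities
are physical), demosaiced, 4×4 binned, and white-normalized against a
Spectralon-style reference cube, in that order. A 2048×1088 frame
becomes a 512×272×16 reflectance cube.

Demosaicing uses weighted bilinear interpolation implemented as
normalized convolution: per band, the native samples (a stride-4
lattice) are zero-filled and convolved with the separable triangle
kernel `(1-|d|/4)` for `|d|<4`, then divided by the identically
convolved sample-indicator. Shifted triangle kernels at stride 4 form a
partition of unity, so the scheme is exact on affine images, reproduces
native samples exactly, and near the border simply renormalizes the
available weights. Binning averages (not sums) so the reflectance scale
is independent of the binning factor. Coordinates are row-major,
0-based; ROIs are half-open rectangles.

A caveat the tests respect: the simulator renders scenes constant over
each 4×4 tile, so the demosaic→bin round trip is exact (≤1e-6 relative)
only away from tile- or scene-edges where interpolation mixes
neighboring tiles; the exactness check therefore runs on a homogeneous
scene interior.

## Spectrum selection (module `sampling`)

Every spectrum is normalized to its mean intensity (shape, not
brightness, carries the SO2 information). For training, 10 distinct
pixels per cube are drawn uniformly without replacement from the ROI
nearest the probe; for probe comparisons the ROI-mean spectrum is used;
for imaging, a mean-reflectance threshold masks the arm from the
background. Each spectrum is paired with the reference sample nearest
in time (ties to the earlier sample); with a 1-Hz reference the pairing
error is ≤0.5 s, negligible against the physiological time scales.

## Target weighting (module `weighting`)

Occlusion targets pile up mid-range. Targets are binned in ten 10%
intervals (half-open, last bin closed; out-of-range values clamp to the
edge bins since the reference legitimately reports slightly below 0%),
and each bin receives weight ∝ 1/count, normalized to max 1. The
weighted target histogram is flat across occupied bins. Following the
original protocol the weight vector is computed once from the entire
cohort — including the subject later left out. That is a (small,
deliberate) train/evaluation leakage; `weight_scope="train-only"` in
`loso_run` provides the hygienic variant.

## The regressor (module `ann`)

A 16→H→1 network, tanh hidden layer, linear output; H = 3 by default
(selected by the hidden-layer sweep; the error surface over
H ∈ {1,…,20} is nearly flat). Inputs and targets are min-max scaled to
[−1, 1] on the training split. Training minimizes the weighted MSE with
Levenberg–Marquardt: solve (JᵀJ + μI)δ = −Jᵀr with residuals scaled by
√w, accept a step only if the training SSE drops (then μ×0.1, else
μ×10). Defaults mirror the classic toolbox behavior the original
procedure relied on: max 1000 epochs, μ0 = 1e-3, μ ceiling 1e10,
gradient floor 1e-7, and early stopping after 6 epochs without a new
best validation error, restoring the best-validation weights. The
70/15/15 train/val/test split is random at the spectrum level;
`split_random_state` lets repeated trainings share a split while
re-initializing weights (the repetition-stability protocol).
Initialization is layer-width-aware (Nguyen–Widrow style): unit random
hidden directions scaled to tile the [−1,1] input box, spread biases.

Predictions are not clipped to [0, 100]: the reference itself reports
values slightly outside the range, and clipping would bias the
Bland–Altman statistics.

`predict_map` applies per-pixel mean normalization plus the network to a
whole cube; a 512×272 map with H = 3 costs two small matrix products
(milliseconds on one CPU).

## Evaluation (module `evaluation`)

The metric is the weighted RMS error
E_rms,W = sqrt(Σ wᵢ(yᵢ−ŷᵢ)² / Σ wᵢ) with the bin weights above, so each
occupied decade of SO2 counts equally. Leave-one-subject-out: train on
the 19 other subjects' pooled spectra, evaluate on the untouched
subject's full spectrum set (both provocations). Per-phase agreement
follows the occlusion timeline (occlusion at 60–360 s of a 540-s
analysis window): baseline = mean over 0–55 s, end of occlusion = mean
over 300–350 s, release = median of the nine reference-rate samples
centered on the reference peak within 355–410 s, with the network
series resampled (nearest-neighbor) at the same time points — matching
samples, not matching peaks. Bland–Altman bias is the mean per-subject
difference (network − reference; the sample SD, n−1, is used) with
limits at ±1.96 SD. The venous-only ablation retrains on venous spectra
with the same global weights and evaluates on arterial data, probing
extrapolation beyond the training range.

## Synthetic cohort (module `synthetic`)

The simulator emulates the study conditions, not skin biophysics:

- **Optics** — modified Beer–Lambert reflectance
  R(λ) = R_s(λ)·exp(−⟨L⟩·[f_rbc·μa,blood(λ,SO2) + m·μa,mel(λ)]) with
  embedded (coarse, 5-nm) oxy/deoxyhemoglobin extinction tables and a
  power-law melanin term. A single effective path length replaces
  layered Monte-Carlo transport deliberately: the learning method under
  test is agnostic to the true optics, needing only a plausible,
  identifiable sensor→SO2 relationship.
- **Sensor** — 16 Gaussian passbands (≈14 nm wide, centers 460–640 nm,
  weak secondary lobes, per-sensor random perturbation) times a
  broadband illumination spectrum; one shared filter bank per cohort
  because training is camera-specific.
- **Protocol** — baseline plateau ~N(56, 7²)% clipped to [39, 75];
  exponential decay during occlusion to a floor of 0.2–4% (arterial) or
  18–49% (venous); post-release hyperemia peaking at 75–96% (arterial)
  or a modest rebound (venous); RBC tissue fraction rises during venous
  occlusion (pooling). Ranges are calibrated so the reference phase
  statistics resemble a real occlusion cohort.
- **Noise model** (defaults = study conditions): 1% multiplicative
  sensor noise per summed frame, 5%-RMS reference deviation from the
  probe-site truth, a per-subject probe-vs-ROI SO2 offset with 3% SD
  (the probe sits distally from the imaged ROI), 2% SD spatial SO2
  heterogeneity, 15%/10% relative RBC/melanin spatial variation, 1%
  smooth physiological wander, dark level 50 DU. The 3% site-mismatch
  SD is a free parameter (no quantitative value exists to calibrate it
  against) exposed in `NoiseConfig`.
- **Scale** — the desk profile (default) renders 64×64-pixel frames and
  100 cubes per provocation per subject, small enough for the full
  20-subject LOSO analysis in minutes on one CPU; the full-scale
  profile (2048×1088, 760 cubes) reproduces the real geometry. All
  randomness flows from one cohort seed through per-subject
  `SeedSequence` spawns.

What the simulator does **not** emulate — and what passing tests
therefore do not show about real data: layered skin optics and
melanin-regime diversity, real xiSpec filter responses, probe/ROI
motion and tracking, vessel structure, and temporal noise correlation
in the reference.

## What the desk-scale analysis shows

With the default noise model the irreducible evaluation error against
the noisy reference is ≈ sqrt(5² + 3² + spatial/model terms) ≈ 6%; the
20-fold LOSO mean E_rms,W of the 3-node weighted network lands in the
8–9% range, and a
noise-free-sensor control confirms the ≈5% reference-noise floor.
Repetition spread across 10 re-initialized trainings of one fold is
typically a few tenths of a percent but is seed- and fold-dependent at
desk scale (the evaluation metric is dominated by the sparsely
populated extreme SO2 bins, where different local minima genuinely
differ); see the repository tests and `scripts/acceptance.py` for the
exact numbers computed under fixed seeds.

## Numerical choices and degenerate inputs

- White normalization refuses non-positive white values (naming the
  offending bands) instead of silently adding an epsilon.
- Weight lookup in an empty bin returns 0 with a logged warning;
  all-zero metric weights are an error.
- LM retries with μ×10 on a non-decreasing step or a singular normal
  system; exceeding the μ ceiling ends training with the best weights
  found.
- The release-phase peak window truncates at the window edges (with a
  warning) when the reference peak sits within 4 samples of an edge.
- Bland–Altman requires ≥2 pairs; LOSO requires ≥3 subjects; ROI
  sampling requires ROI area ≥ n.
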