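# Methods

`shadowcyte` implements a label-free pipeline for identifying and
quantifying CD34+ hematopoietic stem/progenitor cells in lens-free shadow
images (in-line holograms recorded directly on a CMOS sensor, without
lenses or staining). This note documents the models, the parameters that
matter, the numerical choices, and the limits of what the synthetic tests
demonstrate.

## Optical simulation (`simshadow`)

A cell is modeled as a circular object of radius `radius_um` with complex
transmittance `a·exp(iφ)` inside the disk and 1 outside; the disk rim is
anti-aliased by fractional pixel coverage so that sub-pixel radius changes
move the pattern smoothly. Illumination is treated as a coherent plane
wave: the physical device's LED-plus-pinhole source is semi-coherent, but
at the short chip-to-sensor distances involved the plane-wave
approximation reproduces the qualitative pattern (bright central maximum,
concentric dark/bright rings). The field is propagated to the sensor with
the band-limited scalar angular-spectrum kernel (evanescent components
dropped), computed by FFT on a 2x zero-padded grid to suppress
wrap-around. Recorded intensity is `background_level·|U|²` plus additive
Gaussian read noise, clipped and rounded to the sensor bit depth. Shot
noise is deliberately not modeled: additive noise keeps every downstream
oracle (linearity, determinism, exact recall) checkable.

Defaults (`OpticalConfig`): wavelength 470 nm (blue LED), frame
1944 × 2592 px, 8-bit depth, background 100 counts, read noise σ = 2
counts. Pixel pitch (2.2 µm) and propagation distance (1.0 mm) are not
device-documented quantities; they were chosen once so that the first
dark ring sits ~8-10 px from the center and simulated PPD values span the
20-80 count range observed on real bone-marrow cells, and both are
config-exposed. With these defaults the first-ring radius estimate
`sqrt(λz)/pitch ≈ 9.9 px` comfortably satisfies the ≥2 px sampling guard;
configurations that violate it raise `SamplingError`.

Cohort generation plants cells of two classes on a regular grid
(minimum separation 3 first-ring radii ≈ 30 px; overlapping cells are
rejected rather than modeled). Class regimes
(`DEFAULT_CLASS_PARAMS`):

| class | radius (µm) | phase (rad) | amplitude |
|---|---|---|---|
| CD34_POS | N(4.2, 0.25) | N(1.8, 0.12) | 0.95 |
| RESIDUAL | N(6.3, 0.5) | N(1.8, 0.15) | 0.95 |

CD34+ stem/progenitor cells are small (~8-9 µm diameter) and optically
homogeneous; the residual mononuclear fraction is larger. A phase of
~1.8 rad corresponds to a plausible refractive-index contrast for cells
in aqueous medium. These regimes place the CD34+ PPD distribution inside
the 40-60 count gate (median ≈ 53) and the residual distribution well
above it (median ≈ 110); they are the fixed study conditions for every
synthetic experiment and were calibrated once, by forward simulation,
before any classifier was trained.

## Object recognition (`detect`)

Background removal subtracts the global frame mean. Segmentation marks
pixels with `|deviation| > k·σ(deviation)`, k = 3 by default: the source
procedure binarizes but states no threshold, and a σ-relative rule is
invariant to illumination level. The described gap-filling ("intermediate
pixels between adjacent foreground pixels become foreground") is realized
as one pass of 3×3 binary closing, unioned with the original mask so the
step can only add pixels. Components are 8-connected (diffraction rings
produce diagonal adjacency); a component is a cell when both bounding-box
sides are in the closed interval [8, 40] px (the verbal rule "8 to 40
pixels or beyond" is contradictory; the closed interval was adopted).
Centroids are computed on the binary mask and rounded with
`floor(x + 0.5)`; 30×30 crops are cut from the *original* frame with the
center on crop pixel (14, 14), and windows that would cross the frame
edge are dropped with a warning.

One addition beyond the literal description: a high-contrast pattern can
shed detached arcs of its outer bright ring that pass the size filter as
separate components. Their centroids land within ~11-13 px of the true
pattern center, so `extract_objects` keeps only the largest component
among detections whose centers are closer than `merge_radius` = 15 px
(half a crop window; two genuine cells this close could not be cropped
separately anyway). Setting `merge_radius=0` disables the rule.

**Operating envelope.** Because the threshold is a global σ multiple,
detection behavior depends on how much signal the frame contains. The
validated regime is ~1×10⁻⁴ cells/px² (a few hundred cells on the
full-size frame) with cell radii ≈ 4.0-6.4 µm at the default optics:
emptier frames push σ down until single patterns over-segment, fainter
cells (< ~4 µm here) fall below 3σ when brighter neighbors inflate σ, and
larger cells shed ring fragments. Detection tests plant cells inside this
envelope; the training cohort, whose crops are cut at ground-truth
centers rather than detected ones, is packed more densely for speed.

## Shadow statistics (`shadowstats`)

The radial profile of a 30×30 crop bins pixels by their rounded Euclidean
distance from pixel (14, 14), giving 15 bins (r = 0..14). Statistics:

* **CMV** — profile intensity at r = 0 (the single center pixel; the
  published per-cell examples are consistent with raw 8-bit values).
* **MMD** — radius of the first strict local minimum of the 3-point
  moving-average-smoothed profile, searched over r ∈ [2, 13]. Smoothing
  suppresses single-bin noise; the end bins are left raw.
* **PPD** — CMV minus the *raw* profile value at MMD. Despite the
  historical name ("peak-to-peak distance") this is an intensity
  difference in counts.
* **SMD** — the profile is recomputed in 8 equal 45° angular sectors
  (the center pixel belongs to all sectors, empty bins are skipped);
  SMD is the population standard deviation of the per-sector MMDs.
  Sectors with no minimum are excluded and logged. No sector scheme is
  documented anywhere for this statistic; 8 sectors is this package's
  choice. SMD needs pixel data, so `compute_params` reports it only when
  the originating crop is passed (`analyze_crop` does this); from a bare
  profile it is 0.

A profile with no interior local minimum (flat, monotone) yields
`valid=False` with zero sentinels rather than an exception. The CD34+
gate keeps records with 40 ≤ PPD ≤ 60, closed on both ends. Boxplot
summaries use type-7 (linear-interpolation) quartiles and Tukey fences at
1.5·IQR.

## Dataset assembly (`dataset`)

The positive class comes from enriched samples of ≥70% purity, so only
CD34+-labeled crops inside the PPD gate are kept; residual-class crops
are not screened. One stated dataset size (10,000 images) conflicts with
another (20,000); resolved as 10,000 per class, 20,000 total. Splitting
is 8:1:1 train/val/test: records are sorted by crop path, shuffled with a
seeded generator (so assignment is invariant to input row order), val and
test sizes are floored and the remainder goes to train — 20,000 records
give exactly 16,000/2,000/2,000. Stratified splitting allocates per
label. Model inputs are 30×30 crops bilinearly resized to 50×50
(half-pixel sample centers: weights sum to 1, so constants and means are
preserved) and scaled to [0, 1] by 2^bit_depth − 1; no per-image
standardization, because absolute contrast is the discriminative signal.

## Classifier (`cnn`)

The network is an AlexNet-style stack: eight 3×3/stride-1/pad-1
convolutions with max pooling (2×2, stride 2, floor) after convs 1, 2, 4,
6 and 8 — spatial trace 50→25→12→6→3→1 — followed by three fully
connected layers (512, 128, 2). Channel widths (32, 32, 64, 64, 128,
128, 256, 256) and FC widths are this package's choices (the source
figure is unreadable at that level) and are config-exposed. Every hidden
layer uses SELU, `λ·x` for x ≥ 0 and `λα(e^x − 1)` otherwise, with
λ = 1.0507, α = 1.6732; weights are LeCun-normal initialized, the
matching choice for self-normalizing networks.

The implementation is pure NumPy — im2col convolutions as BLAS matmuls,
manual backpropagation, float32 parameters. Training is minibatch Adam
(β = 0.9/0.999) on softmax cross-entropy; the optimizer and loss are not
documented for the original model, and Adam/cross-entropy are the
standard pairing. Defaults echo the published recipe: batch 16, learning
rate 5·10⁻⁴, 500 epochs. Per-epoch history records train/val loss and
accuracy; the best-validation-accuracy weights are checkpointed, ties
keeping the earlier epoch. Training is bit-reproducible for a fixed seed.

Grad-CAM backpropagates a one-hot logit gradient to the last (post-SELU)
conv feature map (3×3 spatial), weights channels by the spatial mean of
the gradient, rectifies the weighted sum, bilinearly upsamples to 50×50,
and min-max normalizes; an all-zero map is returned as zeros with a
warning.

## Quantification and agreement (`quantify`)

`classify_sample` runs detect → crop → preprocess → classify over a
sample's frames; the CD34+ percentage is 100·positives/detections. Zero
detections raise an error naming the sample. `compare_to_reference`
takes (reference %, measured %) pairs: R² from simple OLS of measured on
reference (identical to squared Pearson correlation, so the unstated
regression direction is immaterial), differences d = measured −
reference, bias = mean(d), and 95% limits of agreement at bias ±
1.96·SD(d) with the sample (n−1) SD. The mean absolute difference is
reported alongside. A zero-variance reference makes R² undefined; it is
reported as NaN, not raised.

## Problem sizes in the test suite

The suite runs entirely on synthetic data generated at test time. The
training check uses a 2,000-crop cohort (1,000 per class, default
regimes, read noise σ = 2) for 20 epochs at the default architecture,
reaching ≥95% validation accuracy in a few minutes on one CPU; shared
fixtures train a narrower-channel variant of the same 8-conv architecture
(8…64 channels) on 800 crops for 8 epochs. Detection and quantification
tests plant 16-32 cells per reduced frame at the operating density above.

## What the synthetic results do and do not show

The generator reproduces the geometry and contrast structure of real
shadow images and the class-conditional separation of PPD, but real data
differ in ways the simulation omits: partially coherent illumination,
shot noise and fixed-pattern sensor noise, cell clumping and debris,
focus variation, and biological heterogeneity far beyond two
parametrized regimes. Passing tests therefore demonstrate that the
pipeline's machinery is correct and self-consistent — perfect recall on
clean frames, a learnable separable cohort, agreement statistics matching
closed-form oracles — not that the published accuracies on patient
material are reproduced. The published headline metrics (97.3%/96.2%
train/val accuracy, R² = 0.81 against flow cytometry) require the
deposited patient dataset and are intentionally out of scope here; the
optional CLI workflow (`detect`/`stats`/`build`/`train`) can ingest such
data when available.

## Known limitations

* The detector's global σ-relative threshold ties sensitivity to frame
  occupancy; very sparse or very crowded fields degrade it (see the
  operating envelope above). A tiled/local threshold would relax this
  but is not part of the documented procedure.
* Overlapping or touching cells are rejected at generation and not split
  at detection (no watershed).
* PPD's absolute scale depends on the assumed pixel pitch and propagation
  distance; only its ordering behavior (monotone in cell size) and the
  gate logic are meaningful across devices.
* SELU constants are used at published 5-digit precision, not the
  closed-form self-normalizing values.
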