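# Methods

## Problem setting

Collateral status on single-phase CTA is graded from the extent of
vessel filling distal to an occlusion, conventionally by visual scoring
of MIP slices at the ganglionic and supraganglionic levels. The package
automates the imaging side of that task: extract the binarized vascular
morphology from each slice, feed the two levels to a compact CNN, and
characterize how architecture hyperparameters push the classifier toward
sensitivity, specificity, or balance.

## Brain extraction

Input slices are 8-bit images windowed from 0–450 HU
(`hu_to_8bit`: values ≤ 0 HU → 0, ≥ 450 HU → 255, linear in between with
half-away-from-zero rounding), which saturates dense bone so the cranium
occupies the unique top value 255. Steps:

1. **Cranium**: binarize at 255; the largest 8-connected component is
   taken as cranium, making the step robust to isolated bright pixels.
2. **Interior fill**: flood-fill the background 4-connected from the
   image border and invert. 4-connectivity is the topological dual of
   the 8-connected foreground — an 8-connected ring cannot be crossed by
   a 4-connected fill.
3. **XOR** of the filled region with the cranium leaves the enclosed
   brain.
4. **Sobel boundary peeling**: three passes; each pass computes the 3×3
   Sobel magnitude `G = sqrt(Gx² + Gy²)` (border pixels replicated) on
   the *binary* brain-region image scaled to 0/255 and removes mask
   pixels with `G ≥ 255`. Only mask-boundary pixels reach that response,
   so each pass strips exactly one partial-volume boundary layer while
   bright structures interior to the mask — the vessels — are untouched.
   Computing G on the raw grayscale instead would exceed 255 at every
   vessel/parenchyma edge (a contrast of ≥ 64 gray levels already
   saturates the criterion) and delete the vessels from the brain mask,
   making the later vessel AND empty; the binary-image reading is the
   only one under which the downstream segmentation can work.
5. **Opening on leak**: a calvarial defect opens the ring, the border
   fill floods the interior, and the XOR comes back (near) empty — the
   pipeline detects this (enclosed area < 0.5 % of the image), falls
   back to the full non-cranium mask, and separates brain from
   background by repeated morphological opening. Plain 3×3 opening is
   idempotent, so iteration `i` applies `i` erosions followed by `i`
   dilations (an opening by the `i`-times dilated structuring element),
   which severs leak channels up to ≈ 2·i px wide; the loop stops when
   the 8-connected component containing the cranium centroid no longer
   reaches any border pixel, and errors after 10 iterations. Only that
   component is returned.

The final mask additionally excludes every 255-valued pixel, by
construction of the XOR and as a hard postcondition.

## Vessel segmentation (triangle threshold)

Within the brain mask the gray histogram `H_i` has a dominant parenchyma
peak and a sparse bright tail of vessels. The histogram is rescaled to

    NH_i = H_i · (255 − g_peak) / H_peak

so the peak's height equals its gray distance to the top level; with
tied maxima, `g_peak` is the rounded mean of the tied levels. A line
joins `(g_peak, NH_peak)` to `(255, 0)`; the threshold is the gray level
in `[g_peak, 255]` whose histogram point lies farthest from that line in
perpendicular Euclidean distance (ties toward the lower gray level; a
peak at 255 is rejected as degenerate). Binarization is inclusive
(`pixel ≥ threshold`) and ANDed with the brain mask. Design notes:

* The histogram is computed over the brain mask only — skull pixels
  would otherwise dominate the bright end and couple the threshold to
  skull area rather than vessel content.
* The line's right endpoint is fixed at height 0. Using `NH_255` would
  make the threshold depend on however many cranium pixels survive into
  the histogram, contradicting a brain-restricted threshold.
* The perpendicular and vertical point-to-line distances differ by the
  constant factor `cos θ` of the fixed line, so both give the same
  argmax; the canonical perpendicular form is used.
* Scaling all counts by a constant leaves NH's shape and hence the
  threshold unchanged (property-tested).

## CNN family

An architecture is a grid point `(K, F, N_conv, fc, batch)`:
`N_conv` blocks of [K×K 'same' convolution → ReLU → 2×2 max-pool] with
filter counts `F, 2F, …, F·2^(N_conv−1)`, then one dense layer of `fc`
rectified units and a sigmoid output. Default option sets
K ∈ {3,5,7}, F ∈ {8,16}, N_conv ∈ {2,3,4,5}, fc ∈ {64,128},
batch ∈ {8,16,32,64} give a 192-point Cartesian grid. Inputs are the
two binarized level masks resized to 128×128 with nearest-neighbour
interpolation (preserving binarity) and stacked as two channels — the
simplest fusion consistent with one probability per patient.

Training: binary cross-entropy, Adam at 1e-3, shuffled mini-batches of
the grid point's batch size, all randomness drawn from one seeded
generator. Augmentation multiplies each training image by 10: the
original plus nine variants drawn (seeded, without replacement) from
rotations of ±2°, ±4°, ±6°, a horizontal flip, and flip+rotation
combinations; rotated masks are re-binarized at 0.5. Validation and
test images are never augmented.

Early stopping monitors validation AUC with patience 10 (default) over
at most 100 epochs and restores the weights of the **latest** epoch tied
for the best AUC. AUC is invariant to monotone rescaling, so on easy
data the first epoch can already reach the maximal AUC while its
probabilities still sit in a narrow, model-specific band; restoring the
most-converged tied epoch keeps probability scales comparable across
fold models, which matters because the evaluation pools raw
probabilities across test folds. Patience counts strict improvements
only, so a plateau still terminates training.

The engine is NumPy/SciPy: convolutions (forward, input gradient,
weight gradient) are evaluated in the frequency domain with zero-padded
real FFTs, the channel contractions becoming per-frequency batched
matrix products. On one CPU this outperforms an im2col/GEMM
formulation several-fold at 128×128, where the K²-duplicated patch
matrices are pure memory traffic. Forward output and both gradients are
verified in the test suite against a direct `scipy.ndimage.correlate`
oracle and central-difference numerical gradients.

## Evaluation protocol

Patients are split into five folds, stratified by class (an unstratified
split of a 117:40 cohort can produce near-single-class test folds and
undefined AUCs; stratification is switchable). Fold sizes differ by at
most one — a 157-patient cohort yields {32, 32, 31, 31, 31}. Per fold,
the remaining four folds are split 3:1 into training and validation at
patient level (validation = ⌊n/4⌋, stratified). Test-fold probabilities
are pooled into a single ROC; the optimal cut-off maximizes the Youden
index with ties broken toward higher sensitivity, calling a patient
positive when probability ≥ cut-off. Reported per model: AUC
(trapezoidal, equal to the Mann–Whitney pairwise statistic), optimal
Youden, sensitivity, specificity, accuracy, overall performance
`(J* + AUC)/2`, and orientation `sensitivity − specificity`.

Hyperparameter comparisons on a results table: in paired mode (full
grid) a two-sided paired t-test over configurations matched on all other
hyperparameters, with the all-differences-zero case reported as
`t = 0, p = 1`; in unpaired mode (e.g. the AUC ≥ 0.7 subset) groups of
n ≥ 30 use an independent t-test under the central-limit assumption,
smaller groups are Shapiro–Wilk-tested at α = 0.05 and fall back to a
two-sided Mann–Whitney U when normality is rejected.

`rates_to_counts` inverts printed sensitivity/specificity percentages to
integer confusion counts given cohort sizes, warning when the recovered
count cannot reproduce the printed rate at two-decimal precision.

## Phantom generator

A phantom emulates the pixel-level contract the pipeline relies on:
background 0; a skull annulus (default outer radius 110 px, thickness
6 px in a 256×256 frame) at exactly 255; a brain disc with Gaussian
parenchyma (mean mid-range of 70–110, σ = range/6 plus σ = 5 acquisition
noise, clipped to the range) — σ is kept at range/6 so windowing
clipping is a rare-tail event and the histogram stays unimodal, as in
real windowed CTA; vessels as 1–3 px random-walk strokes with correlated
headings drawn from gray 160–220, branching near the two hemisphere
centres. Good-collateral phantoms get 12 branches per hemisphere; poor
ones keep 12 on one side and drop to 3 on the other, mimicking an
asymmetric collateral deficit. The defect variant removes a 5° arc
(~10 px) from the ring. No non-skull pixel can reach 255. Cohorts give
each patient two slices from distinct sub-seeds and a defect flag drawn
at a configurable rate; everything is reproducible from one master seed.

What the phantoms do **not** model: real vessel tortuosity, branching
topology and partial-volume blur; skull-base anatomy, ventricles and
gray/white contrast; beam hardening and contrast-timing variability;
inter-patient variation in skull shape. Consequently, passing the
phantom suite shows the pipeline implements its stated operations
correctly and that the classifier can learn a vessel-density/asymmetry
signal end-to-end — it does not certify clinical accuracy, and the
clinical AUC levels of a real cohort are not reproduced here.

## Problem sizes and numerical choices

* The scaled-down end-to-end check trains the balanced architecture
  (K=5, F=8, N_conv=4, fc 64, batch 16) on 60 phantom patients with
  `max_epochs=5, patience=2` — at this size the task is cleanly
  separable (good/poor vessel-pixel counts do not overlap) and five
  epochs suffice for converged, well-calibrated fold models. Pooled
  five-fold AUC is reported per seed.
* Segmentation recovery is averaged over 20 phantom seeds per condition.
* FFT sizes are `next_fast_len(H + K − 1)`; float32/complex64
  throughout; weight-gradient lags are read modulo the FFT size because
  correlation lags `m − K//2` can be negative.
* Degenerate inputs raise rather than guess: images without a 255 pixel
  ("no cranium found"), all-zero histograms, a histogram peak at 255,
  empty masks, single-class training sets, fewer patients than folds.
* The full 192-point sweep on a clinical-scale cohort is an explicit
  long-running mode (`sweep run` without `--scale`); desk runs subsample
  the grid and cap epochs.

## Known limitations

* The opening loop can erode genuine brain with very wide calvarial
  defects (> ~20 px); such cases end in a `SeparationError` rather than
  a silently wrong mask.
* Pooled-probability ROC remains sensitive to residual calibration
  differences between fold models when training is stopped very early.
* Bit-level reproducibility holds for a fixed BLAS/FFT backend; across
  backends, results agree only to floating-point tolerance.
* The triangle threshold assumes a unimodal parenchyma histogram with a
  sparse bright tail; heavily calcified or contrast-flooded slices
  violate that assumption.
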