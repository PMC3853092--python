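# Methods

## Scope and model

The package treats a multi-neuron fluorescence frame as a single
statistical unit.  It never assigns neurites to individual neurons —
with hundreds of overlapping arbors per frame that assignment is
ill-posed — and instead measures population-level morphology (total and
per-soma masses, skeleton landmark counts) plus generic shape/texture
content.  Dose–response analysis and classification then operate on
those per-frame vectors.

## Segmentation and the 13-feature descriptor

Preprocessing takes four parameters with defaults tuned to 16-bit data:
`contrast = 13`, `soma_intensity = 288`, `neurite_width = 5`,
`particle_cleanup = 15` (the soma threshold exceeding 255 is why frames
are rendered and read as 16-bit).

1. **Background subtraction.**  The background estimate is a grayscale
   opening with a 51×51 window (`background_radius = 25`) applied to a
   Gaussian-smoothed copy (σ = 3).  The smoothing is load-bearing: an
   opening is a min-based filter, and on raw sensor noise it
   underestimates the background by several noise standard deviations,
   which lifts the entire frame past the contrast cut and floods the
   neurite mask.  Residuals below `contrast` are zeroed; output is
   non-negative.
2. **Soma mask.**  Grayscale opening with a disk of radius
   `neurite_width` erases structures thinner than a soma, then an
   absolute threshold at `soma_intensity` and removal of components
   below `particle_cleanup` px.  Overlapping somata merge into one
   component; this is deliberate and mirrors the observed clustering of
   somata at high drug dose.
3. **Neurite mask.**  Binary top-hat: foreground minus its opening with
   the same disk keeps only thin structures; the soma mask is
   subtracted and specks removed.  The opening disk pokes a few pixels
   into each neurite–soma junction wedge, so the mask starts short of
   the soma boundary (see attachment detection below).
4. **Skeleton.**  Topology-preserving thinning to 1-px width.

Landmarks are 3×3 neighborhood operators on the skeleton.  The
neighborhood is encoded as 8 bits in circular order; the number of
*arms* is the number of maximal circular runs of foreground neighbors.
Ending points have exactly one neighbor (one arm).  Branch points have
≥ 3 arms; hits within a 2-px chessboard radius are consolidated to one
reported junction, because thinning smears a physical Y- or X-junction
over 2–3 adjacent pixels.  Attachment points are skeleton pixels within
a contact radius of the soma mask, one per contiguous run; the chain
uses `neurite_width + 3` px to span the top-hat's junction gap plus the
1–2 px the thinning retracts stroke tips.  Degree-1 or degree-3 pixels
inside that contact zone are treated as attachment artifacts, not free
ends or branches.

`neuriteLength` is the skeleton pixel count, not a √2-weighted path
length; on strokes of random orientation this undercounts Euclidean arc
length by ~10% on average (up to ~29% for a purely diagonal stroke),
which is why ground-truth comparisons use a ±15% band on lengths and
areas while landmark counts are compared exactly.  Per-soma averages are
raw features divided by somaCount; when no soma is detected they are NaN
with a logged warning, never an exception.

## Generic descriptors

Lengths depend only on configuration, never content: Zernike
4/9/25/81 (orders 2/4/8/16), Legendre and Tchebichef 9/25/81/289,
polar Fourier 60, Haralick 180, Gabor 60, wavelet 30.

* **Zernike** moments are computed on the unit disk anchored at the
  mask centroid and scaled to enclose the mask; magnitudes are reported,
  giving translation invariance by construction and rotation invariance
  up to rasterization.
* **Legendre** moments use the [−1, 1]² mapping with the
  (2p+1)(2q+1)/(MN) normalization (so λ₀₀ of an all-ones image is
  exactly 1).  **Tchebichef** moments use the orthonormal discrete
  Chebyshev recurrence; orthonormality is machine-exact and is verified
  against a QR-orthonormalized Vandermonde oracle in the tests.
* **Polar Fourier**: |PF(m, n)| for 12 radial × 5 angular frequencies
  about the centroid, all divided by |PF(0, 0)| so the DC entry is 1.
* **Haralick**: the frame is quantized to 8 uniform bins over its
  min–max; for each distance 1–5 the four directional symmetric
  normalized co-occurrence matrices are built and 18 statistics
  (Haralick's 13 classic measures plus autocorrelation, dissimilarity,
  cluster shade, cluster prominence, maximum probability) are summarized
  by their mean and range over the four directions: 18 × 2 × 5 = 180.
  The mean+range reduction is a design decision — the classic
  aggregation that yields exactly 180 values; a flat 18 × 5 × 4 layout
  would give 360.  Degenerate single-bin frames follow point-mass
  limits: contrast 0, ASM 1, correlation reported as 0.
* **Gabor**: 6 orientations × 5 octave-spaced scales (peak frequency
  0.4 cycles/px halving per scale, bandwidth 1 octave), mean and
  standard deviation of the complex response magnitude.  Frames are
  reflect-padded by the kernel half-size so a flat frame has zero
  response sd (no boundary artifact).  Magnitude rather than real part
  is a design decision; the alternative is equally defensible.
* **Wavelet energies**: 10-level 2-D Daubechies-4 (`db4`) transform in
  periodization mode on a frame reflection-padded to a power-of-two
  square (≥ 1024), which makes the decomposition exactly orthonormal —
  the tests verify Parseval to 1e-6.  Features are the mean squared
  coefficient of each of the three detail bands per level.

Shape families read the binary segmentation mask and error on an empty
mask (no centroid); the dispatcher skips them with a warning in that
case while texture families still run.

## Dose–response statistics

Doses are mapped to x = log₁₀(dose in ng/mL) with the untreated control
assigned x = 0.  This convention is what reproduces the published
regression table from the published group means (verified numerically
for four features before freezing), and 0 is the natural control anchor
one decade below the lowest treated dose.

Bartlett's test (α = 0.05) gates between the standard one-way ANOVA and
Welch's variance-weighted ANOVA; a zero-variance group leaves Bartlett
undefined and the feature is flagged heteroscedastic with a warning.
R² = 100·SS_between/SS_total is reported identically in both branches.
Shapiro–Wilk normality p-values are reported per group but gate
nothing.  Note that Welch's F only converges to the standard F as group
sizes grow, even under equal variances — its denominator carries a
finite-sample correction of order 1/n; the tests assert the exact
correction identity rather than naive equality.  Tukey HSD uses the
pooled-variance studentized range in both branches, with compact
letters assigned by insert-and-absorb and verified against the pairwise
decision matrix.

Regression fits both models by OLS on per-image values; in a balanced
design the coefficients equal those from group means (asserted to
1e-9), which justifies refitting the published group-mean table.  The
quadratic is selected iff (R²_quad − R²_lin) > 0.05 × (100 − R²_lin);
`variance_explained` is the share of between-group SS captured by the
selected model's fitted values at the group x's, capped at 100 for
reporting (raw value logged), and `successful` means > 90%.  Cubic fits
are out of scope (mentioned for one feature only in the source study).
Standard errors, when relevant, are per-image-based.

## Classification and feature selection

The SVM is RBF-kernel, one-vs-one, with features z-scored by statistics
of each training fold only (no leakage; the scaling choice itself is a
design decision — the source workflow is silent on it).  The stratified
split rounds the train share half-up per class (36 → 24/12; 7 → 5/2).
Grid search sweeps the 16×16 grid C, γ ∈ {2⁻⁷ … 2⁸}; ties break toward
smaller C, then smaller γ.

IBCGA: population 50, tournament 2, swap-mutation rate 0.05 per gene by
default (all configurable — the source text gives none of these), 20
generations per stage, r from 13 to 1.  Orthogonal-array crossover
treats each differing gene (feature bit, or whole 4-bit SVM gene) as a
two-level factor, evaluates the rows of the smallest Sylvester-Hadamard
L_m(2^(m−1)) array covering the factors, and composes one child from
the best row and one from per-factor main-effect winners; children are
repaired to popcount r by flipping lowest-main-effect bits.  On
inheritance each chromosome drops one randomly chosen selected feature.
The printed Step 7 of the source algorithm says bits flip 0 → 1 while r
*decreases* — contradictory at r = n and with the stated direction; the
package flips 1 → 0 and treats the printed direction as a typo.  CV
folds are fixed per run (seeded) so fitness is deterministic and
cacheable; the fitness cache is keyed by the full chromosome.  The final
solution is the best 10-CV accuracy over all stages, ties toward fewer
features; 30 independent runs (configurable) aggregate into per-feature
selection frequencies.

## Synthetic data: what it emulates and what it does not

Scenes are flat-intensity disks (somata, default peak 600) and
polyline strokes (neurites, default width 3 px, intensity 300) on a
background of 80 with additive clipped Gaussian noise (sd 5), rendered
to 16-bit at 512×512.  Ground truth is computed from the geometry
specifications — disk-union rasterization for soma area, stroke-union
minus somata for neurite area, Euclidean arc length for neurite length,
polyline topology for landmark counts — never from the rendered pixels.
Branches must anchor at interior path vertices (a terminus anchor is a
kink, not a junction).

The dose series uses six doses (0/10/50/100/200/1000 ng/mL — the tables
of the source study print ng/mL, its text once says nM; the tables
win), 36 images per dose.  Trend functions of log-dose set per-image
means: soma count follows the published quadratic arc scaled to ≈ 8–17
per frame (real frames hold hundreds of neurons; the scale-down keeps a
216-image study at minutes on one CPU and is a package choice, not a
property of the method), neurites per soma and per-neurite length
decline monotonically, and the probability of planting a soma
overlapping an existing one rises with dose, reproducing the
soma-clustering signature (merged detections, positive Avg_somaArea
dose correlation).  Per-image parameters vary with a 0.15 coefficient
of variation.  With these defaults the extracted features' ANOVA R²
profile (≈ 59–81%, neurite features highest) resembles the published
table's.

A `separated` layout places somata on a jittered grid with straight,
sector-confined, collision-checked neurites; on such noiseless scenes
every landmark count is exactly recoverable, which is the oracle the
extraction chain is tested against.

Not emulated: point-spread blur, uneven illumination, intensity
vignetting, out-of-focus debris, true arbor geometry (tortuosity,
tapering), and realistic neuron density.  Passing the synthetic
benchmark therefore establishes the *correctness of the measurement and
analysis chain against known geometry*, not segmentation performance on
real micrographs; the published real-data accuracies are not
reproducible without the original images and are not claimed.

## Problem sizes and determinism

Default study size is 216 images (6 × 36) at 512×512; the acceptance
script runs that end-to-end plus a 50-scene recovery benchmark, a
2 000-replicate null calibration of the ANOVA chain, and 10 GA runs
(population 8, 3 generations/stage, 10-fold CV fitness on a 78-row
planted-signal table — the 10-fold fitness matters: coarser folds are
too noisy for the wrapper to shed hitchhiker features).  Every random
choice flows from a single seed through `numpy.random.default_rng`;
fixed seeds give bit-identical images and identical reports.
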