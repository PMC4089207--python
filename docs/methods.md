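# Methods

## Model and assumptions

Speckle in ultrasound is treated as multiplicative noise on an underlying
piecewise-smooth tissue image. The despeckler assumes that, at the analysis
scale, every pixel belongs to one of a small set of local structures —
homogeneous region, bright ridge (linear), dark valley (boundary), isotropic
concentration (spot) — and that these can be told apart from the eigensystem
of the intensity Hessian. A bright curvilinear structure has a strongly
negative major eigenvalue with the major eigenvector across the curve; a
dark one has a strongly positive major eigenvalue; a spot has two large,
similar eigenvalue magnitudes; a flat region has two small ones.

The pipeline per pass: (optional) histogram equalization → Hessian field →
eigensystem → global eigenvalue normalization → classification → refinement
→ structure-matched filtering. Passes compose; the output of one pass is
the input of the next. There is no automatic stopping rule: "clean enough"
is a judgment call, so the pass count is explicit (default 2; a third pass
keeps helping on heavily speckled inputs at some cost to fine detail).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `hessian_sigma` | 1.4 px | scale of the Gaussian-derivative kernels; sets the size of the structures the classifier sees |
| `beta` | 0.12 | T1 threshold below which a pixel is uniform (T1 ∈ [0, 2] after normalization) |
| `alpha` | 0.45 | minimum T1 for the spot class; keeps moderately noisy isotropic responses out of SPOT |
| `epsilon` | 1e−6 | guard in the T2 ratio; far below any meaningful normalized eigenvalue on 8-bit data, and makes T2 = 1 (not 0/0) in flat regions |
| `refine_iters` | 3 | refinement sweeps over the SPOT/UNKNOWN queue |
| `stick_len`, `stick_sigma` | 9 samples, σ = 1 px | oriented 1D Gaussian for linear/boundary pixels |
| `median_size` | 9 × 9 | median window for uniform/unknown pixels |
| `gauss2d_sigma` | 1 px | 2D Gaussian for spot pixels |
| `passes` | 2 | despeckling passes |

`equalize_each_pass` defaults on — the pipeline literally repeats from the
top, and equalization restores contrast that repeated smoothing compresses.
The evaluation harness turns it off, because equalization remaps the
intensity scale and PSNR/SSIM against an unequalized clean reference would
measure that remapping rather than the denoising. Both modes are exposed.

## Numerical choices

- **Derivative kernels.** Separable sampled Gaussian-derivative kernels,
  truncated at 4σ, with discrete moment correction: the order-1 and order-2
  kernels are adjusted to have exactly zero sum and exact unit first /
  double second moment. Without the correction the truncated
  second-derivative kernel has a small nonzero DC sum, and a flat image of
  level 128 acquires a uniform curvature bias (~3e−3) which global
  normalization then amplifies to full-scale eigenvalues; with it, flat
  images classify as uniform and quadratic fields give exact Hessians.
- **Zero-field guard.** Eigenvalue normalization divides by the global
  maximum magnitude only when it exceeds 1e−9 (on the [0, 255] intensity
  scale); below that the field is floating-point residue and is left
  unnormalized with `norm_const = 0`, so featureless images are uniform
  rather than amplified noise.
- **Eigen-decomposition.** Closed-form for symmetric 2×2. Ordering is by
  magnitude; when the two magnitudes tie with distinct values the negative
  eigenvalue is the major one (the bright-structure reading). Eigenvectors
  are sign-canonicalized (x-component ≥ 0, y ≥ 0 when x = 0) for
  determinism; stick filtering is direction-symmetric so only determinism
  matters.
- **Borders.** Whole-sample mirror reflection everywhere (convolutions,
  median windows, stick samples), avoiding spurious boundary responses at
  the frame.
- **Refinement.** The SPOT/UNKNOWN queue is processed in raster order with
  immediate label updates; neighbors are addressed by nearest-pixel rounding
  of p ± v₂ (half-offsets round away from zero); LINEAR relabeling takes
  precedence over BOUNDARY; the queue is rebuilt for each of the 3 sweeps.
  Off-image neighbors are ignored; a zero minor eigenvector leaves the
  pixel unchanged. These choices fix the behavior where sequential queue
  semantics would otherwise be order-dependent.
- **Filtering.** Out-of-place within a pass: every filter reads only the
  pass input, so the result is independent of pixel visiting order. Stick
  samples are bilinearly interpolated (rotation-consistent for oblique
  tangents). The spot Gaussian is evaluated as a full-image convolution
  sampled at spot pixels — identical to a local window for interior pixels
  and vectorizable. Output is clipped to [0, 255]; quantization to 8 bits
  happens only at file write.
- **Equalization.** Classical 256-bin CDF equalization,
  `round(255·(cdf(v) − cdf_min)/(1 − cdf_min))`, on nearest-integer levels;
  single-valued images pass through unchanged.
- **Metrics.** PSNR uses peak 255 with a 100 dB cap at zero MSE. SSIM is
  the reference formulation: 11×11 Gaussian window (σ = 1.5), K₁ = 0.01,
  K₂ = 0.03, L = 255, with a half-window border excluded from the mean so
  padding cannot influence the score; it agrees with scikit-image's
  implementation to machine precision.

## The speckle model

"Rayleigh noise with standard deviation σ" underdetermines a multiplicative
field: a raw Rayleigh variate's mean and standard deviation are locked
together, and a non-unit-mean field would shift overall brightness. The
field here is `n = 1 + σ·Z` with Z a standardized (zero-mean, unit-variance)
Rayleigh variate, clipped at 0, so σ is the coefficient of variation and
brightness is preserved. For a constant image of level I this gives
`MSE = (Iσ)²` exactly, a closed form the tests check by Monte Carlo
(level 128, σ = 0.1 → 25.99 dB). This construction is documented as this
package's reading, not asserted as the only one.

## The phantom generator

`default_phantom_spec` renders what the classifier is built to detect:
three flat vertical bands (levels 60/110/160), two bright ridges (amplitude
90, Gaussian cross-section width 1.8 px), one dark curve (amplitude −50,
width 2.0 px — small enough that the valley never clips at 0, which would
flatten its floor into a uniform region), and four spots (amplitude ±90,
radius 2.5 px). The amplitudes were chosen from the smoothed-Hessian
algebra: a ridge of amplitude B and width w smoothed at scale σ has crest
curvature B·w/(w² + σ²)^{3/2} ≈ 13.7, a spot of amplitude A and radius ρ
has center curvature A·ρ²/(ρ² + σ²)² ≈ 8.3, and a band step of height 50
peaks near 6.2 — so after normalization by the ridge maximum, spot centers
sit at T1 ≈ 0.74, comfortably above α, and flat interiors at ≈ 0. Ground
truth marks ridge centerlines (within 0.6 px), spot centers, and flat
interiors, with don't-care bands around structure borders and band edges
where mixed responses are expected.

The phantom emulates piecewise-uniform tissue with curvilinear boundaries
and isolated reflectors plus multiplicative speckle. It does **not**
emulate depth-dependent attenuation, scan-conversion geometry, spatially
correlated speckle texture, or log-compressed display curves — so passing
tests demonstrate the structural logic of the method, not clinical-grade
performance on scanner output.

## Problem sizes

The test suite and the acceptance script run the full protocol on 256×256
phantoms (the benchmark invariants use 96×96), with one 512×512 field for
the noise-moment and runtime-scaling checks; these sizes put every stage
well inside interactive runtimes while leaving thousands of labeled truth
pixels per class.

## Known limitations

- The classifier is single-scale: structures much wider than
  `hessian_sigma` respond weakly and may be labeled unknown or uniform.
- Thin, low-contrast structures can be erased by the 9×9 median when
  misclassified as unknown (the same trade-off the filtering strategy
  accepts by design).
- Refinement only transfers labels from existing linear/boundary pixels;
  it cannot recover a curve the classifier missed entirely.
- The directional-median and adaptive-weighted-median comparators from the
  wider literature are not reimplemented; the benchmark accepts external
  filter callables instead.
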