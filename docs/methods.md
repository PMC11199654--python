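# Methods

## The imaging model

A single-pixel fluorescence acquisition measures a scene `x ∈ R^N`
(`N = H×W` pixels) through a sequence of spatial modulation patterns: the
detector records `y = A x + n`, where each row of `A ∈ R^{M×N}` is one
pattern and `n` is observation noise.  The sampling ratio `r = m/N` is the
compression level.  Patterns are *bipolar*: every entry is `±1/√N`.  A
binary modulator (DMD) cannot display negative values, so a bipolar pattern
is realized as two complementary binary patterns whose detector readings
are differenced — which is why the differential frame rate is `F = R/(2m)`
for a modulator refreshing at `R` Hz, and the pixel throughput is
`F·N/10⁶` megapixels per second.

## Pattern construction and learning

`patterns.bipolarize` maps a real parent matrix `Φ` to `Sign(Φ)/√N`, with
`Sign(v) = +1` for `v ≥ 0` (zero maps to +1) and `−1` otherwise.
`learn_patterns` optimizes `Φ` to minimize the mean of
`(1/N)‖AᵀA x − x‖²` over a training set — the squared error between an
image and the back projection of its own noiseless measurement, i.e. the
information the pattern set loses on that image distribution.  `Sign` is
non-differentiable; its backward pass uses the straight-through convention
(derivative treated as 1).  Optimization is minibatch Adam
(β₁ = 0.9, β₂ = 0.999, default learning rate 2×10⁻⁴, batch 16).  `Φ` is
initialized i.i.d. standard normal so the initial sign distribution is
symmetric.  The returned operator is the checkpoint with the lowest
training-set loss, so it is never worse than the random initialization.
Training images are normalized by their joint peak before optimization;
the objective is scale-free in `A` but not in `x`, and the normalization
keeps loss magnitudes comparable across scene types.

Step counts default to a desk-scale budget (hundreds of steps); the
full-scale preset (1.5×10⁶ steps) is available in configuration but is a
GPU-class job.  At very small problem sizes (N ≲ 100) a few hundred Adam
steps at 2×10⁻⁴ barely move `Φ`; tests at that scale pass `lr=0.01`
explicitly, which is an optimization-budget choice, not a model change.

## Subsetting, and the zoom mode

`select_subset` keeps `m` of the `M` pattern/measurement pairs (uniformly
without replacement, original order preserved so the pairing stays
auditable).  Because the measurement is linear, the subset satisfies
`y' = A' x` exactly on noiseless data; one acquisition can in principle
yield `2^M − 1` distinct training pairs.

The zoom mode trades spatial resolution of the *patterns* for measurement
count while keeping the field of view.  `merge_patterns` average-pools each
pattern with a `z×z` window and re-bipolarizes on the merged grid
(`128×128 → 32×32` for `z = 4`); `unmerge_patterns` replicates each merged
pixel `z×z` (nearest neighbor) back to the source grid with the source
scale `1/√N_source`.  The two grids are linked by an exact identity: for
any image, `⟨unmerged row, x⟩ = ⟨merged row, block-sum(x)⟩ / z`.

## Measurement simulation

The photon model reflects photon-counting PMT detection of the two
complementary binary exposures: `counts± ~ Poisson(photon_scale ·
⟨pattern±, x⟩)` independently, and the recorded value is
`(counts₊ − counts₋)/(photon_scale·√N)`, an unbiased estimate of the
bipolar measurement `A x` whose variance scales as `1/photon_scale`.  The
source never states a count distribution; Poisson is the physically
standard choice for photon counting and is isolated behind the
`noise_model` enum (a Gaussian alternative exists).  Dark counts and
detector dead time are not modeled — a known limitation.  Scene intensities
are expected photons per pixel per exposure, so the single-photon operating
point (≈400 photons per pattern spread over ≈1000 sample-occupied pixels,
i.e. ≈0.4 photons per valid pixel) is directly reproducible:
`photon_budget` divides the mean total count of the two exposures by the
valid-pixel count.

Seeding is counter-based per measurement row (Philox streams keyed by
seed and row index), so extending an acquisition never re-randomizes
earlier rows.  All module-level randomness fans out from one seed by
stable names.

## Classical reconstruction

`pgd_reconstruct` solves `min_x ½‖Ax − y‖² + λR(x)` by proximal gradient
descent from the parameter-free initialization `x⁰ = Aᵀy`: a gradient step
`z = x − ρAᵀ(Ax − y)` followed by `prox_{ρλR}(z)`.  The ℓ₁ prox is the
closed-form soft threshold; the total-variation prox is solved iteratively
(Chambolle's dual method) to a stated tolerance; `none` is the identity.
The reference regularizers are stand-ins: in the learned solver the prox is
a network.  Iterations stop when the relative change of the estimate drops
below `tolerance` (default 10⁻⁶) or at `max_iters` (default 500).

The default step size is `ρ = 1`, appropriate for near-orthonormal
(Hadamard or learned) pattern sets; the descent guarantee requires
`ρ ≤ 1/‖AᵀA‖`, and for a random bipolar `A` the spectral norm is
`≈ (1 + √(M/N))² > 1`, so convergence tests compute the exact bound with
`spectral_bound`.  If the objective rises while the step size is inside the
guaranteed-descent regime the solver raises an error — that indicates a
defect, not noise.  An optional nonnegativity projection is off by default
to keep the iteration literal.  `least_squares_oracle` (dense
pseudoinversion, guarded to `N ≤ 4096`) is the independent reference for
the unregularized path.

## The unrolled network

The network maps `K` PGD iterations to a feed-forward model, a pure
function of `(y, A, r)` and its parameters:

- **Initialization subnet**: `x⁰ = Aᵀy`, parameter-free.
- **Extraction**: one 3×3 convolution lifts `x⁰` to `C` channels, scaled
  by a learned ratio gate `s(r) = exp(a + b·log r)` (init `a = 0`,
  `b = −1`).  The back projection `Aᵀy` has amplitude roughly proportional
  to `r`, so the gate's initialization `s ≈ 1/r` hands the stages a
  ratio-independent scale and training refines it from there.
- **Stages (K)**: each stage projects the feature stack to an image-domain
  anchor (3×3 conv), applies the *exact* gradient step with a learnable
  per-stage step size `ρ_k`, lifts the result back to features, and adds a
  learned proximal residual (two 3×3 convolutions with a ReLU).  Because
  the physics step is exact, wiring the convolutions to channel-0 delta
  kernels and zeroing the residual blocks makes the whole network reproduce
  classical PGD with identity prox, step for step
  (`UnrolledNetwork.disable_learned`) — the fidelity tests assert bitwise
  equality.
- **Recovery**: one 3×3 convolution back to the image.

`ρ_k` is learnable per stage (a fixed shared value is recoverable as a
special case).  Measurements are not normalized before entering the
network; the checkpoint records this.  Autodiff is an in-repo reverse-mode
tape (`spirecon.autodiff`) with im2col convolutions; gradients are verified
against central finite differences.

**Training** minimizes the mean absolute error `(1/N)‖F(y,A,r) − x‖₁` with
Adam (0.9/0.999), learning rate decayed geometrically from 2×10⁻⁴ to
2×10⁻⁶ over the run, batch 16.  Every time a pair is visited it is
re-subset to a uniformly random `m ∈ {1..M}`, so one model serves every
sampling ratio.  Runs are bitwise reproducible for a fixed seed on a fixed
platform (pure NumPy, deterministic reductions).

**Zoom reconstruction** substitutes the nearest-upscaled merged patterns
for `A` with no architectural change.  The ratio fed to the gate defaults
to `m/N_merged`, not `m/N_source`: upscaled patterns are block-constant, so
`Aᵀy` carries the amplitude of a merged-grid acquisition, and conditioning
on the source-grid ratio would over-amplify by `z²` (measured: it turns the
zoom advantage into a deficit).  Reported sampling ratios remain
`m/N_source`.

## Synthetic scenes

No public data exists for this instrument class, so phantoms emulate its
three sample types at configurable size: **microspheres** (anti-aliased
non-overlapping disks; at 128 px the preset is 13 disks of radius 4.5 px —
a 5 μm bead at the instrument's 20× scale — occupying ≈1000 valid pixels,
the photon-budget scenario), **nucleus** (flat-topped elliptical blobs with
bright internal puncta emulating nuclear speckles), **filaments**
(momentum-random-walk strokes ~1–2 px wide), and **block-constant** scenes
for zoom experiments.  The valid mask is a threshold at
`background + margin`; under the default specs the sparsity ordering
microspheres < filaments < nucleus holds per seed, matching the
observation that the required sampling ratio grows as sparsity falls.  The
μm→px mapping is an estimate read from stated magnification and scale-bar
proportions, exposed as a config default rather than hard-coded truth.

What the phantoms do *not* model: optical PSF and out-of-focus light,
pattern misalignment, detector dark counts, bleaching.  Passing tests
demonstrate the computational pipeline's correctness and its behavior
under Poisson photon statistics — not performance on real instrument data.

## Problem sizes and presets

The `desk` preset (default) uses 32×32 scenes, `M = 200` patterns,
`K = 3`, `C = 16`, 200 pairs (≈4% held out, the proportion of the
full-scale 1150/50 split), 600 pattern-learning steps and 30 training
epochs — minutes on one CPU, and the configuration under which the
training-efficacy properties (trained net beats the `Aᵀy` baseline at
every tested ratio ≥ 0.5%; mean held-out PSNR non-decreasing in `m` within
0.2 dB) are asserted.  The `paper` preset (128×128, `M = 5000`, `K = 9`,
`C = 128`, 1200 pairs) reproduces the full-scale configuration; it is
guarded behind `--allow-large` because training it is a multi-day job.

## Numerical conventions

- `Sign(0) = +1` everywhere bipolarization occurs.
- Bipolar entries are exact: `±1/√N` bit-for-bit, asserted after scaling.
- PSNR uses the ground-truth peak as dynamic range unless given; identical
  images report `inf`.  SSIM uses the standard 7×7 window and constants.
- Frame-rate/throughput arithmetic is exact rational; display rounding is
  a separate helper.
- Statistical tests with several simultaneous comparisons combine per-row
  z-scores into a chi-square statistic at the two-sided 3σ family level.
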