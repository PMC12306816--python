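# Methods

This note records the models, conventions and design choices behind the
package, what the synthetic phantom does and does not emulate, and the
numerical decisions a maintainer would want written down.

## Conventions

All transforms are centered unitary 2D FFTs (`norm="ortho"`, DC at index
`H//2`). Unitarity is load-bearing: unit-variance noise stays unit variance
on both sides of the transform, so the noise level is tracked by a short
scalar chain rather than by re-measurement. Phase encode is the first
spatial k-axis (ky), readout the second (kx); indexing is 0-based. Complex
noise of "SD σ" means real and imaginary parts each have SD σ/√2; the coil
covariance is `Ψ = E[η ηᴴ]`.

## SNR-unit reconstruction

The pipeline is pre-whitening → GRAPPA → coil combination, with one scalar
per step:

1. `Ψ` is the sample covariance of the noise-only pre-scan; the whitener is
   `W = bandwidth_scale · L⁻¹` with `Ψ = LLᴴ`. `bandwidth_scale` (default 1)
   is the hook for a dwell-time/noise-bandwidth mismatch between pre-scan
   and imaging readout; the bundled simulator has none.
2. GRAPPA is calibrated per missing-line offset on the ACS by ridge-
   regularized least squares (default kernel: 4 source phase-encode blocks ×
   5 readout columns; ridge `λ = 1e-4 × mean diag(AᴴA)`). The per-offset
   kernels merge into one composite convolution kernel whose taps at
   `dy ≡ -o (mod R)` serve offset `o`; an identity tap passes acquired lines
   through. Embedding this kernel at the k-space center, inverse
   transforming per (target, source) pair with a `√(HW)` scale, and folding
   with the conjugated unit-norm coil maps gives the image-domain unmixing
   coefficients. The explicit k-space route (circular convolution, then
   IFFT, then combine) is kept as `grappa_fill_kspace` and agrees with the
   pointwise route to machine precision — the two-path oracle that pins the
   embedding convention.
3. Only the regular R-grid lines enter the linear reconstruction (ACS lines
   off the grid are calibration-only). With whitened data, a unitary IFFT of
   k-space nonzero on `n_g` of `H` lines has per-coil pixel noise variance
   `n_g/H`, so after combining with `u` and scaling by `√(n_g/H)` the output
   noise SD is exactly `g(p) = (n_g/H)·rss_c(u_c(p))`.

The scaling convention deserves a sentence: the √R penalty for acquiring
R-fold fewer samples is carried by the *image amplitude* (which drops by
1/√R relative to the fully sampled reconstruction), leaving `g` the pure
geometry factor — `g ≡ 1` at R=1 and `g ≳ 1` elsewhere. This is the
convention in which clinical g-maps are displayed, and it is what makes
`S = I/g` a unit-noise image. The pseudo-replica oracle
(`pseudo_replica_noise_sd`) is the arbiter for this whole chain and agrees
with the analytic map to ~2% median relative error at 256 replicas.

Coil maps come from the Hann-apodized, zero-filled ACS, normalized pixel-wise
to unit norm and phase-referenced to coil 0. Because maps are estimated from
*whitened* data they approximate the whitened sensitivities `W·b` — any
ground-truth comparison must whiten the reference maps first.

Zero-fill resizing pads k-space and multiplies by `√(M_total/N_total)`,
which preserves both the DC level and the average pixel noise SD; the g-map
travels as a variance map (interpolate `g²`, clamp at 1e-6, square root).

## g-factor augmentation

One acquisition's ACS is calibrated at every requested R (2..8 by default);
each calibration is converted to unmixing coefficients and reduced to
`g = (n_g/H)·rss(u)`. When the ACS cannot furnish at least 4× more
calibration equations than unknowns at the 4-block kernel, the source-block
count shrinks to 3 then 2 (recorded per map in provenance). Accelerations
above the coil count proceed but are flagged with a condition-number warning.
`g` is clamped below at 1e-3 before any division.

Two properties are tested rather than assumed: the analytic map equals the
pseudo-replica SD (median relative error < 5% inside the object), and the
object-mean g is non-decreasing in R over {2,3,4,5,6,8} — at the 8-coil
encoding limit the curve flattens near R=7–8, and a single inversion of up
to 2% is tolerated.

## Noise synthesis and pairing

Augmentation draws, in fixed order for exact replay: `σ ~ U[0, 32]`; per
axis, a Gaussian filter width from {0.8, 1.0, 1.5, 2.0, 2.25}; per axis,
partial Fourier with probability 0.5 (ratio from {1.0, 0.85, 0.7, 0.65,
0.55}, truncation side fair-coin); per axis, a resolution ratio from the
same list. The Gaussian filter is `exp(−k̂²/(2σ_f²))` on the normalized
frequency axis `k̂ ∈ [−1, 1]` (half-bandwidth 1), so the listed widths span
strong to mild smoothing. The partial-Fourier taper is a Hann transition
over 10% of the axis at the truncation edge; the resolution mask zeroes the
outer `(1−r)` fraction symmetrically (`⌈r·n⌉` samples survive). Each axis
response is normalized to unit mean-square, which preserves spatially
averaged noise power for every draw (verified to < 3% per draw at Monte
Carlo).

Noise generation follows the pipeline order: white complex noise of SD σ →
pointwise `g_aug` multiplication in image space → k-space filtering →
back-transform; frames are independent (acquisition noise is temporally
white). Composition is `Sn = (S + n)/√(σ² + 1)` applied to the *sum* — the
only reading under which `Sn` returns to unit noise SD (times `g_aug`);
`σ = 0` short-circuits to `Sn = S` exactly. A pair's provenance (the draw,
the chosen R, and a derived noise seed) suffices to rebuild it bit-exactly.

## The phantom: what it emulates, what it does not

The simulator exists so every stage is testable without external data. It
emulates, geometrically, a balanced-SSFP short-axis cine: a body ellipse, a
"myocardium" annulus and a bright "blood pool" (intensity ratio 1 : 0.55 :
0.30) translating sinusoidally with peak displacement `motion_amplitude·H`;
smooth complex coil sensitivities (8 Gaussian lobes of width 0.25·FOV on a
ring, with per-coil linear phase); channel-correlated receiver noise
(exponential covariance, ρ = 0.3) on acquired samples only; a matched
noise-only pre-scan; and an R-grid + centered-ACS sampling pattern. The ACS
is delivered as the temporal average of time-interleaved calibration lines
(noise reduced by 1/√T), as cine calibration practice does — single-shot
noisy ACS makes high-R ridge calibrations shrink toward zero and distorts
the g-vs-R trend. `signal_scale = 100` puts the blood pool near SNR 100 in
the fully sampled reconstruction, a realistic high-SNR cine level.

Not emulated: relaxation and true B-SSFP contrast, off-resonance banding,
respiratory motion, partial-volume anti-aliasing (ellipses are rasterized
binarily so ground-truth labels are exact), readout oversampling, and
non-Cartesian or 2D-accelerated sampling. Passing tests therefore
demonstrate correct *noise* behavior — the quantity this package is about —
under a geometrically plausible object, not fidelity to any particular pulse
sequence.

## Numerical choices and degenerate inputs

- Matrix sizes below 32, fewer than 2 coils, ACS below 16 lines, and R
  outside 1..8 are rejected at configuration time.
- Rank-deficient pre-scan covariance raises an error naming the
  near-duplicate coil pairs; non-positive-definite requested covariances are
  rejected before Cholesky.
- Coil-map normalization guards `rss` at 1e-30; unmixing requires pixel-wise
  unit-norm maps to 1e-6.
- The SSIM settings are a 7×7 Gaussian-weighted window (σ = 1.5), K1 = 0.01,
  K2 = 0.03, data range defaulting to the reference maximum; PSNR uses
  magnitude MSE with MAX = 2048 (images live at unit noise SD, so pixel SNR
  beyond 2048 is implausible). Complex inputs to SSIM are compared on
  magnitudes; real inputs as-is so sign inversions register.
- The pseudo-replica noise floor before SNR division is 1e-6.
- Losses: Charbonnier ε = 1e-3 (its value at zero error); the perpendicular
  loss is `|Im(p·conj(t))|/(|t|+ε) + ||p|−|t||`, invariant to a common global
  phase; the gradient loss sums per-axis mean absolute differences of
  forward-difference magnitude gradients, so a pure ramp-vs-flat pair scores
  exactly the ramp slope. Per-term weights default to 1. No perceptual term
  is included (it would require pretrained network weights).

## Problem sizes

Tests and the acceptance script run the full chain at a 64² matrix, 8 coils,
8 frames, with 128–256 pseudo-replica realizations and 100 filter draws at
128² — sizes at which every Monte-Carlo tolerance is several sampling
standard errors wide while the whole suite completes in well under a minute
of compute.

## Known limitations

- An 8-coil 1D-accelerated array cannot genuinely resolve R ≥ 7; g-maps
  there are dominated by the regularized calibration and should be read as
  "what the reconstruction would do", not as achievable image quality.
- GRAPPA wrap handling is circular in ky; for accelerations that do not
  divide the matrix height the grid spacing is irregular across the wrap,
  which perturbs reconstruction fidelity (not the noise bookkeeping) near
  the k-space edge.
- The noise model is complex Gaussian throughout; magnitude (Rician)
  statistics, physiological noise, spikes and drifts are out of scope.
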