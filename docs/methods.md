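# Methods

This note describes the model implemented by `deepsuvr`, the synthetic
phantom used to exercise it, and the numerical and design choices made
where the method leaves them open.

## Background and model

Amyloid-PET burden is usually quantified as an SUVR — mean tracer
uptake in a cortical target region divided by mean uptake in a
reference region (classically the whole cerebellum) — and reported on
the Centiloid (CL) scale, a per-tracer affine rescaling anchored at 0
(young-control mean) and 100 (typical-AD mean). Despite this
harmonisation, residual variability between tracers, scanners and
reference-region physiology propagates directly into CL values and
especially into longitudinal CL rates.

The core of the package is a correction model that multiplies the
standard SUVR of a scan by a scalar correction factor CF ∈ [0, 2]
predicted by a small 3D convolutional network from the SUVR-normalised
image and a one-hot tracer code. The network is trained **without any
ground-truth target**, purely from longitudinal self-consistency over
within-participant visit pairs (3 months to 3.5 years apart, all
eligible permutations):

* `Ld = max(0, CL_T0 − CL_T1)` — amyloid burden does not decrease in
  observational cohorts;
* `Lc = |(CL_T1 − CL_T0)/Δt − fc((CL_T0+CL_T1)/2)|` — the annual rate
  should match the natural-history curve `fc` at the pair's mean level;
* `Ls = |s − 1|`, `Li = |i|` — slope and intercept of the batch-level
  regression of corrected on uncorrected CL, anchoring the corrected
  scale to the standard one and preventing collapse;

combined as `L = mean(Ld) + α·mean(Lc) + β·Ls + γ·Li` with α = 0.2,
β = 1, γ = 0.01. The curve `fc` is a LOWESS smooth (span 0.2, tricube
weights, one robustness iteration, evaluated on a 256-knot grid and
interpolated linearly, clamped outside the observed support) of
(mean CL, CL/year) points from standard quantification, restricted to
the unbiased anchor tracer (PIB), and is **frozen before training**.
Both images of a pair pass through the network in the same iteration
in randomised feed order; time order alone defines T0/T1. Training
uses Adam, early stopping on the validation loss, and best-of-N
restarts selected by the validation Spearman correlation between mean
corrected CL and corrected CL/year.

The architecture stacks stride-4/kernel-4 convolutions (channels
16→128 at full scale) with instance normalisation and leaky
rectification (slope 0.01), flattens, concatenates the length-5 tracer
one-hot, applies two fully connected blocks (dropout, affine, batch
normalisation, tanh) and a final affine layer squashed through
`2·logistic`, so CF ∈ [0, 2] by construction. The number of
convolutional blocks is derived from the grid — blocks are stacked
while every axis still spans a full kernel, capped at four — because a
stride-4 kernel cannot act on an axis shorter than 4 voxels: the
91×109×91 (2 mm) template grid gets a 3-deep stack (91→22→5→1), the
32×40×32 (4 mm) desk grid a 2-deep stack. Hidden widths (256, 64 at
full scale) are free parameters recorded in the config.

## Mask derivation

To re-express the learned correction as an interpretable quantification
rule, continuous reference and target masks are optimised by gradient
descent so that their SUVRs correlate maximally, per tracer, with the
corrected SUVRs: `Lp = mean_tracers(1 − R²)` plus a binarity penalty
`Lb = Σ_brain(0.5 − |M − 0.5|)/B` with weight δ = 5·10⁻⁴, boosted
×100 after 20 full-batch passes. Gradients of the SUVR ratio and the
Pearson statistic with respect to mask voxels are analytic. After each
step masks are clamped to [0, 1], mirrored to exact left–right symmetry
(averaging with their reflection), and restricted to the brain mask; a
3-level multiresolution schedule (×4, ×2, ×1 image downsampling with
mean pooling, trilinear mask upsampling) runs each level until the
windowed `Lp` improvement falls below 10⁻⁸ after a per-level minimum
iteration count. Final mask SUVRs are recalibrated per tracer to the
corrected-SUVR scale by least squares before the standard Centiloid
transform is applied.

Two numerical choices depart from a literal reading of the procedure
and are deliberate:

* the 4 mm Gaussian kernel is applied to the **gradient update** (and
  once to the initial masks) rather than to the evolving mask at every
  iteration. Per-iteration mask smoothing compounds — the effective
  kernel width grows with √iterations — and reduces any mask to a
  near-uniform blur within ~50 iterations, which the binarity gradient
  (order δ/B per voxel) cannot counteract; smoothing the update retains
  the spatial-consistency intent while leaving converged masks
  stationary, so the fixed-point property (targets generated by the
  initial masks leave the masks unchanged) holds.
* on the desk grid the multiresolution schedule is (×2, ×1): the desk
  grid is itself 4× coarser than the full template grid, and a further
  ×4 pooling destroys the thin cortical shell (its down-up roundtrip
  Dice is 0.32, versus 0.91 at ×2), making the coarsest level
  counterproductive at this scale. Full-scale configurations keep
  (×4, ×2, ×1).

## The synthetic phantom

The phantom emulates, at desk scale, exactly the failure modes the
correction is meant to fix. A 32×40×32 (4 mm) ellipsoidal brain
contains a cortical shell target and an inferior cerebellar-analogue
reference made of a grey blob and a white blob. Uptake is piecewise
constant, blurred with the scanner PSF (Gaussian, FWHM ≤ 8 mm), and
perturbed with voxel noise; every scan is SUVR-normalised by the whole
reference mean.

* **Trajectories.** True burden follows a logistic natural history
  `CL(t) = 100/(1 + exp(−(t − onset)/τ))` with τ = 3 years; 10% of
  participants are flat non-accumulators. The time constant is
  deliberately compressed relative to the human disease (where the
  0→100 CL transition takes decades) so that cohorts of one to two
  hundred pairs — rather than tens of thousands — carry a measurable
  trajectory signal; rates scale accordingly (peak ≈ 8 CL/yr). Onset
  (72 ± 5 y) and baseline age (72 ± 5 y) concentrate participants in
  the dynamic range.
* **Signal.** The upper shell expresses the full specific signal
  (amplitude 2, so SUVR spans ≈ [1, 3], a PIB-like dynamic range); the
  lower shell expresses 30% of it. The standard target mask covers the
  whole shell, so the "clean" quantification uses the upper shell only
  — a recoverable hidden target.
* **Reference pathology.** The white blob's level varies across scans
  (σ = 3% around the grey level), emulating variable non-specific
  white-matter binding; the grey blob is stable. The clean reference
  is therefore the grey blob alone — a recoverable hidden reference.
* **Scanner model.** Each participant is scanned on one scanner (PSF
  drawn uniformly from 5–7 mm FWHM) with a 20% per-visit probability
  of moving to a different scanner. Same-scanner follow-up is the norm
  in the cohorts this regime emulates; scanner changes are the main
  source of longitudinal rate outliers.
* **Tracer bias.** A tracer's reference-region uptake can be inflated
  by a factor k (both blobs), deflating its standard SUVR by ≈ k. The
  default mix is 75% PIB (unbiased anchor) and 25% of a biased tracer:
  in the pooled multi-study regime the anchor tracer dominates and any
  biased tracer is a minority, which is what lets the batch-level
  anchor regression pin the unbiased scale.
* **Calibration.** Per-tracer Centiloid transforms are anchored
  (negatives → 0, saturated → 100) on noise-free, unbiased renderings
  at the mid-range PSF — the published-calibration setting. A
  study-specific reference bias is absent from calibration by design,
  so it survives as the residual quantification bias the network must
  learn to remove.

The amplitude-2 dynamic range matters quantitatively: a reference bias
of 1.15 then offsets a negative scan by ≈ −6.5 CL, against ≈ −13 CL at
amplitude 1. With the published loss weights, the anchor terms grow
linearly with that offset while the curve-prior signal does not, and at
amplitude 1 the loss minimum sits at CF = 1 even noiselessly — the bias
would be unrecoverable by construction, not by optimisation failure.
These conditions were fixed from a loss-landscape analysis (grid search
over constant per-tracer CF) before any recovery experiment was run.

What the phantom does **not** model: anatomy, partial-volume effects
beyond Gaussian blur, scatter/reconstruction effects, off-target
binding, and motion. Passing recovery tests therefore demonstrates that
the losses identify and remove reference-region and resolution biases
under controlled conditions — not that any particular real tracer needs
a 15% correction.

## Desk-scale training protocol

The reference training protocol (batch 128, learning rate 10⁻⁴,
dropout 0.5, early-stopping patience 20, five restarts) is built for
~10⁵ visit pairs on a GPU. At a few hundred pairs on one CPU core that
regime does not transfer: with dropout 0.5 the systematic loss signal
(of order 10⁻³ per scan per step) never escapes the gradient noise and
the network stays at CF ≡ 1, while the full-width network simply
memorises each scan's noise pattern. The desk protocol
(`DESK_TRAIN_CONFIG`) therefore uses a capacity-matched network for the
desk grid (channels 8→16, hidden 32→16, no dropout), learning rate
10⁻² with step decay (×0.3 at 60% and 85% of the epoch budget), and two
forms of stochastic regularisation that substitute for the reference
protocol's scale and augmentation:

* fresh additive Gaussian voxel noise per iteration (σ = 0.05), which
  makes a scan's noise pattern unlearnable while preserving resolution
  and uptake-pattern cues;
* optional random-resolution augmentation via precomputed smoothed
  variants of each training volume, the cheap equivalent of the
  reference protocol's random-smoothing augmentation. Randomising
  apparent resolution prevents the network from sculpting per-scan
  corrections out of fine image detail (a curve-overfitting mode: with
  a frozen, slightly misfit `fc`, a sufficiently flexible per-scan
  correction can bend every pair onto the curve and beat even the
  ground-truth correction on the training loss), at the price of
  resolution-correction ability.

The full geometric augmentation (rotations ≤ 5°, coarse non-rigid
warps with control-point σ = 20 and magnitude 50 in full-scale voxels,
scaled proportionally to the grid, plus PSF-aware smoothing up to the
8 mm quadrature ceiling) is implemented and unit-tested but disabled in
the recovery experiments: the phantom has no spatial-normalisation
error to model, and per-image warping is the single most expensive step
at desk scale.

Problem sizes used by the recovery experiments (chosen as the package's
study conditions): bias recovery trains on 200 participants × 2 visits;
identity recovery on 100; the bias-preservation retraining on 200; the
cross-sectional peak comparison evaluates on a separate 300-participant
single-visit screening-style cohort with 50% negatives; the outlier
band is derived from a 100-participant single-scanner PIB cohort,
mirroring the way the reference range is defined on a same-scanner
subsample.

The bias-preservation experiment (10% of participants given halved
inter-scan intervals, i.e. exactly doubled uncorrected rates, then a
full retraining) is judged out of sample, on held-out participants, and
with a level-matched statistic: each accelerated pair's rate is divided
by the normal subgroup's fitted rate-vs-level curve at the same mean
CL, and the median of these per-pair ratios is normalised by the same
statistic computed over the normal subgroup itself (which equals 1 by
construction, so the normalisation removes curve-estimation bias).
Comparing raw subgroup median rates instead is dominated by which
trajectory stages the ~20 flagged participants happen to occupy, and
in-sample evaluation lets pair-specific overfitting masquerade as
over-correction.

## Known limitations

* The longitudinal losses identify the correction only up to
  transformations that preserve trajectory consistency; the anchor
  regression removes the global affine freedom but a soft ratio-versus-
  common-mode trade-off between tracers remains at desk scale. In
  recovery runs the learned biased-tracer correction is typically 60–80%
  of the injected bias, with the remainder absorbed by level-dependent
  per-scan corrections.
* LOWESS gives no uncertainty on `fc`; the curve is treated as exact by
  the loss.
* The HSIC permutation test uses the biased empirical estimator with
  median-heuristic bandwidths; p-values are resolution-limited by the
  number of permutations.
* Checkpoints store NumPy arrays; no cross-version weight portability
  is attempted.
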