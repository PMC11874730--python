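# Methods

This note documents the models, numerical choices and known limitations
of the package, in the order data flows through the pipeline.

## Spiral trajectory design

The acquisition model is a center-out variable-density spiral with
`n_arms = 13` interleaves per real-time frame (TR 3.7 ms, 48 ms frame
footprint). The published constraint is the azimuthal undersampling
factor R(|k|): ≈5 at the k-space center rising to ≈15 at the edge. The
interleaf law itself is not public, so the package adopts the simplest
profile reproducing the constraint: R varies **linearly** in |k| between
`center_undersampling` (default 5) and `edge_undersampling` (default 15),
and the interleaf solves

    dk/dθ = n_arms · R(|k|) / (2π · N),   N = FOV / resolution,

because Nyquist-rate azimuthal sampling at radius k requires
`2π·N·(dk/dθ)` identical interleaves. The arm is resampled to constant
arc-length spacing (constant readout speed); the sample count derives
from the readout timing (TR × 70 % duty ÷ dwell, with dwell = 1 /
(pixel-bandwidth × matrix) — 540 samples for the full-scale geometry) and
is set explicitly (256) on the small desk grids. Coordinates are
normalized to cycles/pixel in [−0.5, 0.5); images are row-major,
origin top-left, package-wide.

*Rotation schedule.* Pattern p+1 is rotated so its arms bisect the
currently largest angular gap of the union of all previous arm angles,
ties broken by the smallest gap start angle; offsets are reported modulo
2π/13. This reproduces the sequence 0, π/13, π/26, 3π/26, … and after 8
patterns leaves 104 distinct arms with maximum gap 2π/104 · 2 or less.

*GSTF.* Gradient correction is a frequency-domain multiplication of the
waveform spectrum with a measured (here: synthetic — unit-magnitude
delay plus first-order low-pass, labelled as such) transfer response,
followed by trapezoidal moment integration to k-space. Triangular
rewinders null the zeroth moment including the junction trapezoid.

*Density compensation* estimates each sample's k-space area as
along-track arc spacing × distance to the nearest sample on any other
arm (floored at a quarter of the arc spacing where arms converge at the
center), normalized to unit mean. For radial-like geometries this is
proportional to |k|, matching Voronoi cell areas to a few percent.

## Encoding and CG-SENSE

The forward model is `y_c = F_k (S_c · x)`. `F_k` is implemented as
2×-oversampled FFT + Kaiser-Bessel interpolation (width 6, Beatty shape
parameter) with quadrature-computed deapodization; the adjoint is the
exact conjugate-transpose of the same linear map, so the operator pair
passes the inner-product test at the gridding-accuracy level (≤1e−3) and
an explicit DFT-sum mode passes at machine precision. Forward gridding
agrees with the brute-force non-uniform DFT to ≈1e−5 relative error on
16×16 grids.

The interim image is 10 plain conjugate-gradient iterations on the
unregularized, unweighted normal equations (no density preconditioning;
an optional per-sample weighting argument exists but defaults off).
Complex images are carried through CG-SENSE; magnitude is taken only at
the network boundary. Gridding previews combine coils by conjugate-map
weighting with an ε = 1e−8 floor on the sum of squared magnitudes.

Coil maps for reconstruction are estimated Walsh-style from the temporal
average of an early 104-arm segment: block-smoothed (8 px) outer
products, per-pixel dominant eigenvector, unit root-sum-of-squares,
phase referenced to coil 0; optional 4× spatial subsampling with linear
interpolation back.

## Self-gating

The first readout sample of every arm (k = 0) gives a per-arm DC
navigator, root-sum-of-squares over coils, detrended by a 2 s moving
average. Trigger detection is coarse-to-fine: a 0.5–3 Hz zero-phase
Butterworth band-pass locates the dominant cardiac frequency f0; a
narrow second pass (0.55–1.7 f0) suppresses waveform harmonics and
identifies beats with a 0.6/f0 minimum separation; each trigger is then
refined to the local maximum of the wide-band signal within ±0.25/f0.
Interior triggers recover simulated (including lognormal-RR arrhythmic)
beat times and RR intervals to within one pattern duration (48 ms);
triggers within ~0.5 s of the signal edges are unreliable because of
filter transients, which the tests therefore exclude.

Arms are binned by linear time fraction within their RR interval
(default 20 phases); heartbeats with RR outside median ± 40 % are
discarded, and assigned + discarded arm counts are conserved. Segmented
assembly takes, per accepted heartbeat, the 13-arm frame lying entirely
inside that beat whose mean phase is closest to the request — whole
frames only, so each contribution carries a single pattern orientation
and 8 heartbeats yield 104 distinct arm angles. Real-time frames are
matched to self-gated phases by the bin covering their phase fraction.

## Synthetic phantom

The generator emulates the two data sources the model needs and the test
sessions it is judged on:

* **Geometry.** Concentric circles for LV blood pool and myocardium, a
  crescent (offset disk minus epicardium) for the RV with a thin wall,
  and a chest-wall fat band. Contraction follows a raised-cosine law in
  cardiac phase with end-systole at phase 0.35; myocardial cross-section
  area is conserved while the cavity contracts. All regions have
  analytic areas, so EF has a closed form: for the default radii (24 mm
  ED, 16 mm ES) EF = 100·(1 − (16/24)²) = 55.6 %.
* **Pixelization.** Masks are rendered area-preservingly: sub-pixel
  coverage is computed on an 8× supersampled grid and, per region,
  pixels are selected by descending coverage until the rounded total
  coverage is reached. Mask pixel counts therefore track analytic areas
  to within one pixel, and the stored LV area is the coverage integral.
  Images blend tissue intensities by coverage (anti-aliased).
* **Sessions.** Arms are emitted in acquisition order, 13 per 48.1 ms
  frame; the object is rendered once per frame (cardiac motion within
  48 ms is below the method's temporal resolution). Breath-hold mode
  rotates the pattern at each heartbeat after at least one full RR
  (cycling after 8 orientations); free-breathing mode cycles orientation
  per frame, adds sinusoidal in-plane translation, and draws each RR
  lognormally (σ = `rr_variability`; 0.12 is the default arrhythmic test
  condition). Complex Gaussian k-space noise is specified as a fraction
  of the DC magnitude (0 = noiseless, the default for the analytic
  recovery experiments).
* **Training pairs** replay the published simulation chain: random
  smooth coil sensitivities (ring of Gaussian lobes with phase ramps),
  forward NUFFT on the 13-arm pattern, 10 CG-SENSE iterations → interim
  input; the clean frame and its labels are the targets. In the desk
  recipe the CG step uses Walsh-*estimated* (unit root-sum-of-squares)
  maps rather than the generating maps, so training interims carry the
  same estimation imperfections and intensity shading as deployed
  reconstructions of acquired sessions — without this the model sees a
  domain shift at inference and systematically dilates small
  structures.

What the phantom does **not** emulate: bSSFP signal physics and banding,
through-plane motion, trabeculation, papillary muscles, realistic
receiver noise correlations, and real anatomical variability. Passing
tests therefore demonstrate the correctness and internal consistency of
the pipeline, not clinical performance.

## Disentangled model

Input images are interim magnitudes normalized to [0, 1] by their 99th
percentile. The anatomy encoder is a U-Net (depth 2, base width 12 at
desk scale — deliberately small so a full training run fits a single
CPU core; both are config fields and scale up for larger grids) whose
8-channel output is channel-softmaxed and thresholded at 0.5 with a
straight-through gradient. The segmentor is exactly three 3×3
convolutions with batch normalization and LeakyReLU, then a 1×1 softmax
classifier over {background, LV, myocardium, RV}. The modality encoder
(stride-2 convolutions → global average pool → linear) sees the image
concatenated with the binary factors (a flag disables this) and returns
an 8-dim Gaussian posterior; training draws a reparameterized sample,
inference uses the mean. The decoder applies three convolution + FiLM
(per-channel scale/shift projected from z) + LeakyReLU blocks to the
binary factors. The refinement U-Net reads the decoded image stacked
with the interim magnitude and predicts a **residual** added to the
interim — restoration starts from the identity, which is what lets the
refined output undercut an already-good interim within a short training
budget.

Losses (weights in `ModelConfig`, defaults seg 10, KL 0.01, modality 1,
reconstruction 1): soft Dice + cross-entropy on the segmentation; the
closed-form KL of the modality posterior; an L1 between the modality
sample and its re-encoding from the decoded image; and a reconstruction
loss combining mean-squared feature distances over a frozen, seeded
3-level random convolutional pyramid with a pixelwise L1 term (weight
1). A random-feature perceptual metric keeps the build self-contained;
no pretrained backbone is assumed.

The whole network is built on a small reverse-mode autodiff engine
(`spiralcine.nn`): conv2d via im2col + GEMM, fused batch normalization,
nearest-neighbor upsampling, straight-through binarization, Adam. All
gradients are finite-difference-checked in the test suite.

## Training

Each epoch pools all acquired-session samples with a fresh
without-replacement draw from the simulated pool (282 per epoch at full
scale), shuffles, and applies random H/V flips combined with a rotation
from {0°, 90°, 180°, 270°} identically to input, target and mask. Epoch
composition is a pure function of (seed, epoch). Defaults: Adam,
lr 1e−4, batch 8, 200 epochs; validation splits by session, never by
frame. The **desk-scale recipe** (`experiments.run_desk_training`) is
the configuration the acceptance experiment runs: 200 training frames at
64×64 (20 virtual subjects × 10 phases; per-subject geometry spans
base-to-apex sizes, ED radius 14–28 mm, and contrast jitter), 24
held-out frames from independent subjects, 30 epochs, lr 1e−3 (suited to
its ~750-step budget), seed pinned. The best-validation checkpoint (LV
Dice − refined NRMSE) is kept.

## Cardiac function

LV volume per frame is label-1 pixel count × pixel area × 8 mm slice
thickness. The volume curve is smoothed with a 3-frame moving average;
maxima/minima are detected with a 300 ms minimum separation and
alternation is enforced by keeping the more extreme of adjacent
same-type extrema. Per slice, EDV/ESV are the medians of the
maxima/minima values; volumes sum over slices;
EF = 100·(EDV − ESV)/EDV. The median makes the estimate robust: one
±50 % corrupted cycle among six moves EF by under 1 % absolute.
Dice, NRMSE (normalized by reference range), PSNR (∞ sentinel for
identical images) and SSIM (scikit-image, reference dynamic range) are
provided as generic quality metrics. RV and myocardium masks are
reported but never auto-summarized into clinical indices.

## Problem sizes and reproducibility

Desk-scale defaults — 64×64 grids, 256 samples/arm, 4–12 s sessions,
depth-2/width-12 networks, 30 epochs — are chosen so the complete test
suite, including the training experiment, runs on one CPU core in tens
of minutes; the full-scale geometry (512 matrix, 540 samples/arm, depth
and width scaled up, 200 epochs) is reachable through the same configs.
All randomness flows from explicit integer seeds (sessions, coils,
subject geometry, model init, VAE sampling, epoch composition);
reconstruction is deterministic and frame-order independent.

## Known limitations

* Plain CG on the normal equations converges slowly for strongly
  variable-density sampling; density-weighted CG or preconditioning
  would sharpen interim images but is deliberately not the default.
* No off-resonance/B0 correction, no banding handling, no 3D
  trajectories, no slew-rate/amplitude constraint optimization.
* Trigger timing inherits the 48 ms frame granularity of the simulated
  DC navigator and degrades at the signal edges.
* The perceptual loss uses random features; with a pretrained extractor
  the reconstruction term would better reflect perceptual quality.
* EF from a single short-axis slice (or a 3-slice stack) is an
  area-driven surrogate; full-coverage stacks are simulated per-slice
  independently rather than as a coherent 3D heart.
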