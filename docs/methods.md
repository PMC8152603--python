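# Methods

This note documents the models, estimators and numerical choices behind
`wmstates`, and what the synthetic benchmark does and does not establish.

## Task model

The simulated task is a blocked two-item orientation working-memory design.
Each block fixes two memory orientations drawn from a 16-point grid
(2.8125° … 171.5625°, 11.25° spacing) under the constraint that the pair is
neither identical nor orthogonal; each of the block's 16 trials presents an
auditory retro-cue (Markov cue sequence with configurable switch probability,
default 0.5), a 700 ms delay, and a probe grating from a second 16-point grid
(8.4375° … 177.1875°). The 5.625° offset between grids puts the decision
variable — the acute angular distance between probe and cued item — on an
8-level support, 5.625° … 84.375°. Intertrial intervals are exponential,
truncated to 400–900 ms, with the rate solved by bisection (tolerance
10⁻⁹ ms) so the truncated mean equals a configured value (default 550 ms);
achievable means lie strictly between 400 ms and the 650 ms midpoint.

One deliberate departure from a fully i.i.d. design: the first item of each
block cycles through shuffled copies of the grid rather than being drawn
independently, so that every orientation recurs as a memory item. Item-label
decoding with leave-one-block-out cross-validation requires every relative
orientation bin to be populated in every training fold; with i.i.d. item
draws that fails with high probability at desk-scale block counts. Balanced
coverage is the design the decoding analysis presumes. Orientation
convention: 0° = vertical; by symmetry no computation depends on it.

## Generative EEG model

Epochs span −200 … +2600 ms around cue onset at 250 Hz, with the target at
+800 ms. Each trial is a sum of spatial-pattern × temporal-envelope ×
trial-amplitude components plus noise:

| component | spatial code | envelope | amplitude |
|---|---|---|---|
| active (cued item) | item tuning map | smooth step from 200 ms, ×(1 + bump 900–1300 ms) | `amp_active` · gain_cued |
| latent (uncued item) | independent latent map (or shared, configurable) | raised cosine 900–1300 ms | `amp_latent` · gain_uncued |
| lingering reactivation (uncued item, switch trials) | **active** map at the uncued orientation | raised cosine 900–1300 ms | `amp_linger` · gain_linger |
| target orientation | independent target map | raised cosine 870–1370 ms | `amp_target` |
| decision variable | fixed channel vector | ramp from 1050 ms | `amp_dv` · (dv − 45°)/45° |

Orientation patterns are `tuning_map @ (cos 2θ, sin 2θ)` with orthonormal
tuning-map columns, so every pattern has unit norm and amplitudes are in
noise-SD units. Noise is multivariate Gaussian with a random SPD spatial
covariance (condition number ≤ 50, unit mean variance) and an AR(1) process
over samples (default coefficient 0.8, stationary marginal covariance equal
to the spatial covariance). Optional eye channels carry independent white
noise and no task signal, for the confound-control analysis. Encoding gains
are lognormal with median 1 (log-SD 0.3 per item and trial).

Three structural choices deserve emphasis, because naive alternatives break
the intended phenomenology:

1. **The active code has target-evoked temporal structure** (the
   magnification bump). The spatiotemporal decoder removes each trial's
   per-channel mean over its 100–400 ms post-target window, so a purely
   sustained code would be invisible to it; empirically the cued code is
   magnified by the probe, and the generator reflects that.
2. **The target code uses its own tuning map.** If the probe's evoked
   response shared the item map, target-evoked activity would masquerade as
   cued-item decoding with a sign that tracks the decision variable,
   inverting the planted decoding→behavior association.
3. **Interference is carried by a dedicated lingering component**: on switch
   trials the previously acted-upon (now uncued) item is re-expressed in the
   *active* format with its own heavy-tailed gain (lognormal, mean 1, log-SD
   1.2). Its trial-to-trial fluctuation, not its mean expression, couples to
   behavior; a mean-dominated coupling would confound the uncued decoder's
   switch-trial offset with the switch cost in RT and fake an uncued→RT
   association that the benchmark requires to be null.

## Behavioral model

Responses come from a two-boundary Wiener diffusion (σ = 1, symmetric start).
Per trial the drift magnitude is (v₀ + v₁·dv) scaled by a within-block
fatigue decrement, a cardinal-axis penalty, and — in the matched-filter
coupling mode — the cued-item encoding gain (drift strictly proportional to
gain, the literal matched-filter statement). The non-decision time collects a
switch cost, lingering-gain interference on switch trials, and — in the
head-start mode — the cued-item gain. Responses beyond the 4000 ms deadline
are recorded as missing. Defaults (a = 1.2, t₀ = 0.30 s, v₀ = 0.2,
v₁ = 0.025/°, switch cost 80 ms, fatigue 1 %/trial, cardinal penalty up to
20 %) place the observer near the empirical operating point of such tasks —
roughly 77 % correct and 640 ms mean RT in the demo configuration. The
coupling amplitudes (γ = 1, interference 0.06 s per unit lingering-gain
excess, linger amplitude 0.25) were calibrated once, during design, so that
the planted effects yield group-level effect sizes of the magnitude the
analyses are meant to detect (|d| ≈ 0.5–1.5 at 10 subjects × 32 blocks), and
then frozen.

Simulation uses Euler–Maruyama at dt = 0.5 ms with the Broadie–Glasserman–Kou
continuity correction (boundaries contracted by 0.5826·σ√dt when testing
crossings). Without the correction the discrete-crossing bias inflates mean
decision times by ≈ 2.6 % at this step size, which is detectable against the
closed-form zero-drift mean first-passage time at n = 50,000.

## Decoding estimators

All decoders share the same machinery. Per training fold (leave one block
out): noise residuals are each trial's deviation from its orientation mean,
averaged over 0–1800 ms post-cue; their Ledoit–Wolf shrinkage covariance
(one covariance per fold, not per timepoint) defines the Mahalanobis metric.
Training trials are binned by orientation relative to the test trial's label
(equivalently: per-orientation means re-indexed per test trial) and averaged;
the 16 distances from the test pattern are mean-centered and sign-reversed
into a tuning curve. Readouts: the cosine vector mean with angle doubling
(orientations are 180°-periodic), or, for the 8-level linear decision
variable, the sign-reversed OLS slope of similarity against absolute label
distance. If the residuals are identically zero (noiseless fixtures) the
covariance degenerates to the zero matrix and the estimator falls back to
the identity metric with a warning.

The time-resolved decoder runs this at every 4 ms sample; subject-level mean
time courses (only) are smoothed with a reflection-padded Gaussian kernel,
SD 24 ms. The spatiotemporal decoder instead builds one feature vector per
trial from the half-open window [100, 400) ms post-target: per-trial
per-channel mean removal, block-averaging of 10 consecutive samples (an
anti-aliasing downsample; the incomplete trailing block is dropped — 75
samples → 7 blocks, e.g. 17 channels → 119 features), then the identical
Mahalanobis machinery in feature space. The cross-item decoder trains its
bins on cued-item labels and evaluates each test trial at its uncued label.
Spatiotemporal indices are left unsmoothed. Eye-based decoding series are
regressed out of EEG series by per-subject OLS across timepoints with the
intercept retained.

## Linking models

RT models are OLS on ln RT (ms), correct responded trials only; accuracy
models are logistic, all responded trials, with an L2 fallback (penalty
10⁻⁶) on separation. Decoding scores are centered within block before
entering any trial-wise model; covariates are block number and trial within
block. Block-wise models use leave-one-trial-out block means of the decoding
strength of the test trial's cued item, split by whether that item was cued
or uncued on the other trials. The noise-matching control scales both score
vectors by the cross-item SD, adds Gaussian noise with
SD = √max(0, Var(regular) − Var(cross)) to the cross vector, refits the
trial-wise model per injection and averages weights (the degenerate
direction rescales instead, with a prominent warning). The cross-item
regression replaces the regular uncued regressor with the cross-item score,
keeping the cued score and covariates. Group inference is the
summary-statistics approach: one-sample t tests (one-tailed in the
theoretically predicted direction — facilitation for cued, interference for
uncued/cross) and JZS Bayes factors on per-subject weights.

## Group statistics

The cluster-permutation test forms clusters from contiguous runs where the
pointwise one-sample |t| exceeds the two-tailed α = 0.05 criterion (the
cluster-forming threshold and the summed-t mass statistic are declared
defaults, configurable), and corrects against the permutation distribution
of the maximum absolute cluster mass under subject-wise sign flips, with the
add-one convention so corrected p ∈ (0, 1]. Note two small-sample
properties: with n subjects there are only 2ⁿ flip patterns (n = 5 cannot
reach p < 0.05), and with very large true effects near-identity flips keep
large masses, so ≥ 8 subjects are needed for the demo effect to clear
α = 0.05. The JZS Bayes factor integrates the noncentral-t likelihood over a
Cauchy prior (scale √2/2) on the standardized effect by adaptive quadrature;
one-tailed variants truncate and renormalize the prior.

## Regression drift-diffusion model

The hierarchical, empirically-informed prior structure of common DDM
toolboxes is out of scope; the package fits a documented single-level
Bayesian model per subject (or pooled across subjects as a fixed-effects
approximation to a group posterior): parameters (a, t₀, v_intercept,
v_slope, β), likelihood the Wiener first-passage density (small-time /
large-time series, switching at scaled time 0.35, ±7 terms each), priors
a ~ N(1.5, 1²) > 0.3, t₀ ~ N(0.4, 0.3²) > 0.05 s, drift terms and
β ~ N(0, 5²). β enters the drift (target `drift`) or the non-decision time
(target `ndt`). Sampling is adaptive random-walk Metropolis: diagonal scale
tuning toward ~30 % acceptance in the first half of burn-in, then a
multivariate proposal (2.38²/d × empirical covariance) learned from the
second half; adaptation stops at the end of burn-in so the retained chain is
Markov. 5000 draws, first 1000 discarded. Start point fixed at z = 0.5;
no inter-trial variability parameters. Evidence for a coupling is the
posterior directional mass of β, with ≥ 95 % on one side of zero read as
significant and anything below as not.

On matched-filter data the `ndt` fit can weakly mimic the drift coupling
(high-gain trials are faster, which a negative t₀ slope partly captures);
across replicate experiments the ndt mass scatters widely around ~0.55–0.65
and only rarely approaches the 0.95 criterion, so "null channel below the
significance criterion" is the stable reading of the dissociation, rather
than a point prediction of exactly 0.5.

## What the benchmark shows — and does not

Passing tests establish that each estimator recovers the structure its
generator plants, at the planted effect sizes, under Gaussian AR(1) sensor
noise and a correctly specified label grid. They do not establish
performance on real EEG: no volume-conduction topography, artifacts,
filtering distortions, non-Gaussian noise, nonstationarity across blocks, or
deviations of real memory codes from the (cos 2θ, sin 2θ) pattern model are
simulated; eye channels are decorrelated noise rather than realistic
oculomotor signals, so the confound regression is exercised only as
machinery. The false-positive calibrations (cluster family-wise error;
trial-wise regression under zero coupling) are the parts that transfer most
directly, since they hold under the null regardless of effect structure.

## Problem sizes

The test suite runs everything at desk scale, as the package's own choice of
benchmark size: demo experiments use 10 subjects × 32 blocks (512 trials);
calibrations use 200 replicate experiments (cluster test: 20 subjects × 100
timepoints × 500 permutations; regression: 10 subjects × 128 trials each,
with the diffusion simulated at dt = 2 ms under the null, where
discretization accuracy is immaterial); full-scale sessions (128 blocks,
2048 trials, 10,000 permutations) are supported by the same code paths and
exercised where cheap (session generation, ITI sampling). Noise-matching
tests use 10–20 injections instead of the default 1000.
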