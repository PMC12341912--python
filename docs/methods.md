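# Methods

This note documents the models and procedures implemented in `catrep`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data tests do and do not establish.

## Data model

An `EpochSet` holds `trials × channels × timepoints` amplitudes in
microvolts with a millisecond time axis locked to stimulus onset (default
span −150..+500 ms) and per-trial labels (task ∈ {superordinate, basic},
category ∈ {bird, nonbird_animal, vehicle}, correctness — possibly missing
for no-response trials — RT, participant). All window arguments are closed
intervals on sample latencies. Channel order is authoritative from the
source file; no montage-based reordering is performed. Trials without a
response are retained for all EEG stages and excluded only by the
behavioral RT filters, since both correct and incorrect trials enter the
multivariate analyses.

Epoch conditioning:

- **Baseline correction** subtracts the per-trial, per-channel mean over
  −150..0 ms (idempotent by construction).
- **Eye-artifact rejection** removes trials whose maximum absolute
  instantaneous difference between the two vertical EOG channels exceeds
  150 µV. The reduction to a scalar per trial is not uniquely determined by
  the "difference > 150 µV" convention; the maximum over the epoch is the
  conservative reading and is what is implemented. Rejection is applied
  after baseline correction; the ordering is recorded in the EpochSet log.
- **Equal-trial subsampling** draws, per label group, the minimum group
  count uniformly without replacement from an explicit integer seed. The
  library never draws from unseeded global state.
- **Time binning** (temporal generalization) averages every *k* consecutive
  samples, drops the trailing remainder (floor division), and assigns
  block-center latencies.

## Synthetic generator

The generator exists so that every downstream stage has a
parameter-recovery test against known ground truth. It emulates:

- **Design**: 2,000 trials per participant, 1,000 per task; category mixes
  25/25/50 (bird / non-bird animal / vehicle) in superordinate blocks and
  50/25/25 in basic blocks.
- **Behavior**: an accuracy-coded drift-diffusion model per task ×
  category, with boundary separation *a*, drift *v*, non-decision time *t*,
  diffusion coefficient fixed at *s* = 1 (the scale convention of common
  hierarchical DDM tools, so drift units are comparable), and unbiased
  start *z* = a/2. Integration is Euler–Maruyama at dt = 0.5 ms with two
  bias reductions: linear interpolation of the crossing time within the
  crossing step, and a Brownian-bridge correction that absorbs paths
  crossing a boundary inside a step with probability
  exp(−2(b−x₀)(b−x₁)/(s²dt)). With the correction, simulated choice
  probabilities agree with the closed-form absorption probability
  (1−e^(−2vz/s²))/(1−e^(−2va/s²)) within Monte-Carlo error at n = 20,000.
  The fitted parameter magnitudes of the original study are not published
  numerically, so the defaults (a = 1.4, t ≈ 0.3 s, v between 1.8 and 3.0)
  are arbitrary-but-plausible values yielding high accuracy and RTs of
  0.4–0.7 s, with the qualitative structure the study reported (drift lower
  at the basic level for bird and non-bird animal, higher for vehicle;
  boundary task-invariant; non-decision time slightly longer for basic
  non-bird animals).
- **EEG**: each trial is `effect_uv · M · latent_mean(task, category, t)`
  plus noise. The latent geometry places the three categories on an
  isoceles triangle, so the declared pairwise distances are Euclidean by
  construction: bird/non-bird separation is 0 in the superordinate task and
  ramps linearly 0 → 1 over 250–350 ms in the basic task; both categories'
  separation from vehicle ramps 0 → 1 over 120–180 ms identically in both
  tasks. Ramps are linear between breakpoints because only onsets, not
  shapes, are constrained by the hypothesis being emulated. The default
  mixing is M = Σ^½Q with Q orthonormal and Σ the spatial noise
  correlation: the planted separations are thereby defined in
  noise-whitened (discriminability) units, so after multivariate noise
  normalization the measured separations equal the scheduled ones
  regardless of which latent direction an effect occupies — without this,
  "equal across tasks" control contrasts would not be null under
  correlated noise, because the animal/vehicle difference vector
  necessarily changes direction between tasks (exact direction invariance
  is geometrically impossible when the bird/non-bird split changes). The
  exact channel-space separations implied by the drawn mixing are recorded
  in the `GroundTruth`. A group can share one mixing (common anatomy,
  required for group-level source analysis) or draw one per participant;
  with shared anatomy, the small direction-dependent residue of *estimated*
  (shrunk) whitening is consistent across participants and can register as
  a tiny between-task difference in the control pair — an identifiability
  limit of measured-distance comparisons, so the specificity study uses
  per-participant mixing where that residue is exchangeable.
- **Noise**: stationary multivariate Gaussian with exponential spatial
  correlation over a ring channel layout (e-folding 0.5 rad) and optional
  1/f temporal coloring (on by default, marginal SD restored after
  coloring). Defaults are `noise_sd_uv = 8`, `effect_uv = 20`: single-trial
  ~2.5-SD channel-space separations at full ramp, which produce peak
  pairwise decoding accuracies around 0.9–0.95 — a deliberately
  high-signal regime appropriate for recovery testing. Real EEG category
  effects are far weaker; passing recovery tests here demonstrates
  correctness of the machinery, not sensitivity at realistic effect sizes.
- **Participants**: one synthetic participant per seed; groups are lists of
  independently seeded sessions, which makes participants the exchangeable
  units the group-level tests assume.
- Fabricated Gaussian "posterior" chains centered on true DDM parameters
  stand in for hierarchical-model posteriors when testing the
  posterior-overlap statistic; the hierarchical fit itself is out of scope.

## Behavioral statistics

d′ uses the log-linear correction (add 0.5 to each cell, 1 to each
denominator) so it stays finite at floor/ceiling rates; it is antisymmetric
under swapping signal and noise. Paired contrasts are two-sided paired
*t*-tests with paired-data Cohen's d and Bonferroni correction (default
family of 3). A constant nonzero difference yields infinite *t*; its p is
reported at the smallest positive float rather than 0. The posterior
overlap probability uses index-paired draws for equal-length chains
(preserving MCMC dependence) and the full cross-product otherwise, with
ties counted 0.5. Hit rates for distractor categories are ambiguous in the
literature; both the yes-rate and the correct-rejection rate are computed
and labeled.

## Cluster-based permutation inference

Pointwise paired *t* statistics (units = participants) are thresholded at a
two-sided cluster-forming p < 0.05 (the common convention of permutation
testing tools; configurable), contiguous suprathreshold points of the same
sign form clusters with mass = summed *t*, and each observed cluster's
|mass| is compared to the permutation distribution of the maximum |mass|
over both sign families. Permutations are within-unit sign flips of the
condition differences (n_perm default 1,000; exact enumeration of all 2ⁿ
flips when n ≤ 12 against zero). p = (1 + #{null ≥ obs})/(1 + n_perm) for
sampled permutations, the count-based ratio for exact enumeration.
2D grids use 4-neighbor (face) connectivity, and optionally nonsignificant
points fully enclosed by a significant cluster are filled into the mask
(flood-fill from the border, matching standard image-fill behavior).
Zero-variance points get ±∞ *t* capped at the largest finite |t| in the
dataset to keep masses finite. Calibration: over 200 synthetic null group
datasets of 17 participants, the family-wise error at α = 0.05 falls inside
the binomial 95% interval [0.02, 0.09] (checked in the acceptance suite).

## Decoding

Per timepoint, the channel vector (no temporal window) feeds a two-class
LDA: w ∝ Σ̂⁻¹(μ₁ − μ₂), with Σ̂ the pooled within-class covariance under
analytic (Ledoit–Wolf) shrinkage toward the scaled identity. Shrinkage is
on by default because average-referenced channel sets make the pooled
covariance rank-deficient; shrinkage 0 (pseudo-inverse fallback) is
available for the unregularized convention. The bias places the decision
boundary through the class-mean midpoint; exact-zero decision values break
toward the second class (fixed, documented). Each repetition (default 10)
re-equalizes trial counts and re-draws stratified folds (default 10) so
every fold has equal class counts; accuracies are averaged over folds then
repetitions. The shuffled-label baseline permutes labels independently per
repetition before fold assignment — an empirical chance distribution that
is more conservative than a fixed 0.5. Temporal generalization first bins
time by 4, then applies each train-time classifier at every test time with
the same folds; its diagonal reproduces timepoint decoding exactly.
Decoding the same category across tasks is deliberately not implemented:
tasks were run in separate blocks, and block-level noise differences could
masquerade as representational differences.

## Cross-validated RSA

Distances are **squared** cross-validated Euclidean distances — the
cross-validated inner product has no unbiased square root, so the squared
convention is kept throughout and stated on the outputs. Per iteration
(default 20), each condition's trials are randomly partitioned into 5
pseudotrials; fold k takes pseudotrial k of each condition as the test pair
and the remaining means as the training pattern:
d_k(t) = (ā_train − b̄_train)·(a_k − b_k). Because train and test
differences carry independent noise, the estimator's expectation is 0 for
identical conditions; sample values may legitimately be negative.

Multivariate noise normalization estimates the within-condition residual
covariance per timepoint with Ledoit–Wolf shrinkage, averages the estimates
over timepoints (scope configurable to per-timepoint), and whitens all
trials by Σ̂⁻¹ᐟ². Whitening is computed once on the equalized single-trial
data before pseudotrial formation — matching the description of
normalization applied "to these trials" — rather than nested inside each
cross-validation iteration; the whitener is condition-symmetric, and the
null simulations in the acceptance suite confirm the estimator's mean
remains within Monte-Carlo error of zero under this choice.

Windowed dissimilarity matrices (30-ms windows, default centers 50..400 ms
by 50 plus 480 ms) retain negative entries; classical MDS double-centers
the signed matrix and reports the full eigenvalue spectrum, so negative
(non-Euclidean) structure and dimensionality loss are visible to the
caller rather than silently clipped. A numerically zero matrix embeds as
coincident points; a matrix with a strictly negative spectrum raises.
Procrustes alignment to a reference configuration is provided for plotting
only, since MDS solutions are defined up to orthogonal transforms.

## Source statistics

LDA weights are converted to activation patterns with the Haufe transform,
pattern(t) = Σ_x(t) w(t) / var(w·x), which for LDA equals the ERP
difference between the decoded conditions up to scale (verified: cosine
> 0.95 per timepoint on well-conditioned synthetic data). Per-participant
patterns are normalized to unit Frobenius norm before group averaging so no
participant dominates (configurable). The group pattern is fit per
timepoint as a simultaneous ordinary least-squares combination of all area
templates ("simultaneously submitted" is read as joint least squares; a
non-negativity option exists but is off by default since it is not part of
the described procedure). The null flips each participant's whole pattern
with probability 0.5 (the participant is the flip unit; per-timepoint flips
would destroy the temporal structure the method needs) and refits;
localization is linear, so per-participant coefficients are computed once
and recombined, making 1,000 draws cheap. A Gaussian is fitted to the null
per area and timepoint; z = (obs − mean)/SD, p = 2(1 − Φ(|z|)), and
significance requires p < 0.005 sustained for ≥ 15 consecutive
milliseconds (a run of k samples counts as k·1000/srate ms). Note the
sign-flip z saturates at √P for a perfectly consistent effect across P
participants, so the p < 0.005 rule needs roughly P ≥ 9 even for noiseless
effects — group sizes comparable to the emulated study (17) are assumed.
The construction of real area templates is external; any areas × channels
matrix supplied as TSV works, and the packaged fixture is synthetic smooth
ring topographies with pairwise |cos| < 0.95.

## Pipeline and reproducibility

`run_pipeline` executes simulate → behavior → ERP → decode → temporal
generalization → RSA/MDS → sources from one validated config (unknown keys
rejected, violations reported with their config path). Every stochastic
stage receives a child seed derived by hashing (master seed, stage name,
indices), so enabling or reordering stages never shifts another stage's
stream, and a rerun with the same config is byte-identical. Outputs are
plain TSV/JSON; the manifest records parameters, child seeds, wall times
and SHA-256 checksums.

## Problem sizes used in validation

The validation studies run at desk scale, chosen to finish in minutes on
one CPU while keeping the tested properties meaningful: family-wise error
over 200 null datasets × 17 participants (40 trials/task, 8 channels);
estimator unbiasedness over 100 null simulations; onset recovery over 20
replicate groups of 17 participants (the emulated study's analyzed group
size) × 600 trials × 32 channels at 256 Hz; demo pipeline with 5
participants, 200 permutations and bootstrap draws. Statistical conclusions at these sizes
transfer to larger runs because every component scales only its
Monte-Carlo precision, not its logic.

## Known limitations

- The generator's noise is Gaussian and stationary; real EEG has
  non-stationary, heavy-tailed artifacts, and passing recovery tests here
  does not demonstrate robustness to them.
- Effect time courses are piecewise-linear ramps; latency estimates on real
  data depend on effect shape and SNR in ways the synthetic benchmark does
  not probe.
- Upstream preprocessing (filtering, re-referencing, ICA, channel
  interpolation) is out of scope: data are assumed to arrive epoched and
  clean.
- The hierarchical Bayesian DDM fit is not implemented; the
  posterior-overlap statistic consumes externally provided (or fabricated)
  posterior chains.
- Cluster inference controls family-wise error over time (or time × time)
  only; no channel-space clustering or TFCE.
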