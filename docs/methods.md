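# Methods

This note documents the models, numerical choices and limitations behind
`blockmvpa`. It is written for users who want to know what the package
computes and what its synthetic benchmarks do and do not demonstrate.

## The analysis problem

A subject alternates between two self-driven mental tasks in 32-s blocks
separated by 16-s rest, while whole-brain BOLD volumes are acquired every
TR = 2 s. Each subject completes 12 sessions; session types alternate
between a Countdown/negative-memory pairing (Type A) and a
Countdown/positive-memory pairing (Type B), with 3 cycles of
task/rest/task/rest per session (144 scans after discard). The question
is whether a *single* 2-s scan carries enough information to identify
the task being performed, and where in the brain that information lives.

## Decoding model

Scans from acknowledged task blocks (start cue answered within 2000 ms,
strict `<`) are extracted with block onsets shifted by 2 TRs to allow for
hemodynamic delay, and encoded either as the vector of all in-mask voxel
values ("voxel" encoding, dimensionality = mask size) or as 116
region means over an anatomical parcellation ("region" encoding).
Datasets are strictly balanced at the block level: if a block is not
acknowledged, its counterpart block (same ordinal block of the other
task in the same session, or in the paired adjacent session for the
memory-vs-memory comparison) is excluded as well, whether or not it was
acknowledged itself.

The classifier is a soft-margin linear SVM with C = 1 (libsvm via
scikit-learn). Before each fit, every feature is affinely mapped so that
its *training* minimum and maximum land on −1 and +1; the identical map
is applied to test data without clipping, and features constant in
training map to 0. Cross-validation is leave-one-session-out within a
subject (adjacent-session pairs for memory-vs-memory, since the two
memory tasks never share a session) and leave-one-subject-out across
subjects (restricted to voxels common to all subjects). Accuracy is the
pooled count of correct test scans over all folds, c/(c+e).

Ties at a decision value of exactly 0 predict the positive class; this
rule is arbitrary but fixed for determinism.

As a descriptive view of the classifier's temporal behavior, each
fold's decision values are also evaluated over *all* scans of the
held-out session(s) — rest scans included, although they never enter
training or testing — normalized per fold to [−1, 1] (a constant fold
maps to 0, and the normalization runs over all scans of the held-out
session, not task scans only, since the display includes rest periods),
then averaged within and across subjects into a mean decision
time course with its per-scan SD.

## Inference

**Balanced-block permutation test.** Scan labels are exchangeable only
at the block level (scans within a block share slow hemodynamics), so
the null distribution is built by relabeling whole blocks, uniformly
among assignments that preserve the per-unit class counts (unit =
session, session pair, or subject — the same unit that guarantees
balance). For each of `n_perm` draws the entire cross-validation is
rerun. Because the [−1, 1] scaling depends only on training *features*,
the per-fold linear-kernel Gram matrices are invariant under label
permutation; the implementation precomputes them once and refits the SVM
per draw, which is exactly equivalent to the naive rerun (asserted by a
test) and orders of magnitude faster. The reported p-value is the
add-one Monte Carlo estimator p = (1 + #{null ≥ observed})/(1 + n_perm),
which is valid and never zero.

**Precision.** The 95% interval for a pooled accuracy with c correct and
e incorrect scans is the equal-tailed quantile interval of
Beta(c+1, e+1) — the posterior under a uniform prior.

**Encoding comparison.** Per-fold (within) or per-subject (across)
accuracies under the two encodings are compared with a two-sided
Mann-Whitney-Wilcoxon test, exact for samples of ≤25 without ties,
normal approximation otherwise.

## Interpretability maps

The weight vector of each fold's linear SVM is re-projected onto the
grid (*discriminating volume*): a positive voxel pushes decisions toward
the positive class. Fold volumes are divided by their in-mask SD
("unit variance" — no mean subtraction, so zero weights stay zero),
averaged into a subject map, smoothed with an 8-mm-FWHM Gaussian
(per-axis sigma in voxel units, truncated at 4σ, zero-padded at the grid
edge), and averaged across subjects without re-standardization.

The mass-univariate reference is a GLM with one boxcar ⊗ canonical-HRF
regressor per task (acknowledged blocks only), six motion parameters,
one constant per session, and a per-session DCT basis below 0.0078 Hz;
serial correlation is optionally handled by pooled-coefficient AR(1)
prewhitening (a single lag-1 coefficient estimated from in-mask OLS
residuals, applied per session, then refit) rather than voxelwise ReML —
a desk-scale simplification. Contrast T-maps use
T = c'β̂ / √(σ̂² c'(X'X)⁻¹c); group maps are voxelwise one-sample t over
subjects (dof = n−1). Similarity between a group T-map and the group
discriminating volume is the in-mask voxelwise Pearson correlation.

The canonical HRF is a double gamma (peak 6 s, undershoot 16 s, unit
dispersions, peak:undershoot 6, 32-s support), sampled at TR and
normalized to unit sum so a long block's plateau response is exactly 1 —
pattern amplitudes are therefore in sustained-signal units. The same
kernel object drives both the generator and the GLM, which is what makes
noise-free parameter recovery exact to numerical precision.

## Preprocessing

Stages run in a fixed order on all sessions of a subject, and an audit
log records that order:

1. **Nuisance regression** — per voxel, OLS residual against the six
   motion parameters, the mean of a 3-mm sphere in white matter and in
   CSF (in the original study at MNI (26, −12, 35) and (19, −33, 18); on
   the synthetic grid, at 30% of the half-extent on opposite diagonals),
   the grey-mask global mean, and one constant per session. Sphere
   membership is by voxel-center distance in world mm, ties included.
2. **High-pass** — per session, residualization on a DCT basis spanning
   frequencies below 0.008 Hz, constant included. Note that a projection
   filter only cancels frequencies exactly in its basis; off-basis
   sub-cutoff components retain a small leakage residual (~8% RMS at
   0.004 Hz for a 288-s session).
3. **Grand-mean scaling** — multiply the session by 100/mean, where the
   mean is the in-mask mean of the *raw* session. Session constants in
   step 1 zero the residual session means, so the raw mean is the only
   well-defined reference; computing the factor before regression and
   applying it after preserves the stated stage order while keeping the
   operation well-posed.
4. **Standardization** — per voxel, z-score against the mean and
   *population* SD of the series concatenated over all sessions, so the
   concatenated series has exactly mean 0 and SD 1 (within 1e-10).
   Zero-variance voxels are zeroed and flagged.

## Synthetic data generator

No scanner data ship with the package; the generator produces datasets
with the statistical structure the analysis assumes. Per voxel:

    offset + Σ_k pattern_k · (boxcar_k ⊗ HRF) + drift + physio
           + global_loading · g(t) + motion_coupling · M(t) + noise

with, per session: a random linear+half-cosine drift (amplitude 2,
signal units — removed by the high-pass), sinusoids at 0.3 and 1.1 Hz
(amplitude 0.5) standing in for aliased cardiac/respiratory power, an
AR(1) global fluctuation (SD 1, loading ≈1 across the mask), a
random-walk 6-parameter motion trace coupled into each voxel, a
Gaussian session-mean offset (SD 5) on a baseline of 800, and white
noise of SD 1. Task blocks are independently unacknowledged with
probability 0.01 (the study reports 9 missed cues in 792 blocks);
acknowledged response times are uniform on [300, 1500] ms, as only the
2000-ms screening boundary matters downstream.

The default grid is 20×24×14 voxels of 3×3×4 mm (a scaled-down analogue
of the full 53×63×35 acquisition grid, which remains available), with an
ellipsoidal "brain" mask partitioned into 116 parcels to mirror an
AAL-style atlas. Activation patterns are per-task random fields:
spatially smoothed ("smooth" style, the default — coarse patterns that
partially survive region averaging) or voxelwise sign-alternating
("fine" style — region means near zero, the regime in which voxel
encodings should outperform region encodings). Patterns are zeroed
within 8 mm of the WM/CSF nuisance spheres: those stand for non-grey
tissue, and planting signal there would make nuisance regression remove
the task subspace itself — an artifact of the simulation, not a property
of the method.

The default pattern amplitude is 0.08 (in-mask RMS, units of the
white-noise SD). The study's true effect sizes are unknown; this value
was chosen so that the default within-subject operating point falls in
the accuracy regime the original experiment reported for real data
(voxel ≈86%, region ≈80% on the scaled-down grid, against reported
means of 82.0% and 75.3%).

What the generator does *not* emulate: spatially correlated noise,
subject-specific HRFs (a single canonical kernel is shared — the study
does not characterize HRF variability), realistic physiological
waveforms, scanner artifacts, or anatomical variability beyond random
per-subject noise. Passing tests therefore demonstrate correctness of
the pipeline's computations and calibration of its inference under the
assumed signal model, not performance on real scanner data — the
original study's headline accuracies are a qualitative reference regime,
not a reproducible target, since its raw data are not deposited.

## Problem sizes

Tests run on a 10×12×8 grid with 2-6 sessions per subject; the
acceptance script uses 4 subjects on the full 12-session paradigm
(within-subject arm) and 4 subjects on a 6-session, 2-cycle paradigm
(across-subject arm, where pooled-SVM permutation reruns dominate cost),
with 99 and 35 permutations. Permutation-test calibration uses 200 null
datasets × 99 permutations at α = 0.05. These sizes are the package's
default benchmark conditions; all are configurable.

## Known limitations

- AR(1) prewhitening uses one pooled coefficient, not voxelwise ReML.
- Cluster/peak tables are descriptive; no random-field or cluster-extent
  correction is provided.
- The balanced-block permutation samples with replacement from the
  constrained space; for very small block counts, draws can coincide
  with the identity labeling, which inflates the minimum attainable
  p-value (an honest property of the test, visible in tiny designs).
- The exact voxel order inside the mask is lexicographic by (x, y, z);
  linear-SVM results are order-invariant, so any fixed order is valid.
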