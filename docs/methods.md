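# Methods

## Problem and pipeline

The package classifies elderly walkers as *apathy* / *non-apathy* from a
single walking micro-Doppler spectrogram. Ground truth comes from the
14-item Apathy Scale: items are scored No/A little/Yes/Very = 0/1/2/3 and
summed; a total ≥ 16 is apathetic (the validated cutoff for the Japanese
version of the instrument). All 14 items use the same uniform mapping; a
`reverse_items`-style variant is deliberately not applied by default, since
the instrument as scored here prints a single mapping for every item.

Classification runs on count features rather than raw pixels:

1. **Channel selection.** One of red/green/blue, or the luminance
   `Y = 0.299 r + 0.587 g + 0.114 b`. `Y` is kept as a real number (never
   rounded) and compared directly with the integer threshold; rounding
   would introduce an undocumented quantization step.
2. **Binarization.** `B_ij = 255` iff `P_ij ≥ threshold`, else 0. The rule
   is *inclusive* (≥, not >): a pixel exactly at the threshold is white.
   Valid thresholds are 0–255; the evaluation ladder is 50…220 in steps of
   10 (18 values). The step size is configurable; 10 matches the
   granularity at which threshold sweeps of this kind are usually reported.
3. **Grid separation and counting.** The mask is partitioned into
   `n_cols` contiguous column strips (time; one per step of the walk) and
   `n_rows` contiguous row strips (velocity bands: stance-phase leg motion,
   body motion, swing-phase leg motion, fast toe/arm motion). The feature
   vector is the column-strip white counts left→right followed by the
   row-strip counts top→bottom — `n_cols + n_rows` values, 8 for the
   default 4×4 grid, 9 for 4×5, 10 for 5×5.

   This *marginal-strip* reading is a design decision: an image "separated
   into four parts by the vertical and horizontal axes" yielding *eight*
   counted parts is only consistent if the four time strips and the four
   velocity bands are counted separately. It also gives the two invariants
   the tests rely on: the column counts and the row counts each sum to the
   total white-pixel count.
4. **Uneven division.** When the image size is not divisible by the grid,
   earlier strips take the extra pixel (deterministic; verified against a
   per-pixel oracle).
5. **Normalization.** By default each count is divided by its strip's
   pixel area, giving scale-free fractions in [0, 1]; raw integer counts
   are available with `normalize=False`.

## Classifiers

All seven models share one contract: `fit(X, labels)` on an
`(n, n_features)` matrix with string labels, `predict(X)` returning labels;
stochastic models are fully determined by their seed, and fitting requires
both classes to be present.

* **SVM** — linear kernel, C = 1 (the method is used as a plain
  maximum-margin linear separator).
* **KNN** — single k = 5 (odd, so binary votes cannot tie), Euclidean
  distance. A per-class pair of k values is not implementable as a single
  well-defined decision rule, so one k is used.
* **Naive Bayes** — Gaussian class-conditionals per feature with the usual
  small variance smoothing; counts are effectively continuous after
  normalization.
* **Decision tree** — binary threshold splits chosen by information gain
  `gain(A) = I(p, n) − E(A)`, no depth limit. The tests verify the root
  split against a brute-force gain computation on a toy table.
* **Random forest** — 100 bootstrap trees, √d features per split, majority
  vote.
* **Neural network** — the five-layer stack 8 → 16 → 32 → 64 → 1: a
  weight-free ReLU applied to the raw features (identity on valid,
  non-negative counts; a guard on invalid ones), three dense ReLU layers,
  one sigmoid output. 2865 trainable parameters at input width 8; the
  input width follows the grid (9 or 10 features for the larger grids)
  while the first dense layer stays 16 wide. Training: binary
  cross-entropy, adaptive-moment (Adam) descent at learning rate 0.001,
  exactly 50 epochs, He initialization, all seeded. Prediction: apathy iff
  the sigmoid confidence is **strictly** greater than 0.5 (a confidence of
  exactly 0.5 is non-apathy).

  Two numerical choices worth recording:
  * *Standardization.* Normalized strip fractions are small (often ~0.02),
    which starves the first layer of gradient in a 50-epoch budget, so the
    network z-scores its inputs with statistics fitted on the training set
    (after the input ReLU, so the identity property of that layer is
    untouched). Zero-variance features get unit scale.
  * *Mini-batches of 32.* Fifty full-batch Adam steps at lr 1e-3 move
    He-initialized weights by ≈ 0.05 — the network would stay at
    initialization and could only express the majority class. Mini-batches
    of 32 (seeded shuffle each epoch, ⌈150/32⌉ = 5 steps per epoch) are the
    conventional default for this kind of small dense network and give the
    50-epoch budget enough optimizer steps to learn. Batch size, epochs,
    learning rate and hidden widths are all constructor arguments.
* **Ensemble** — majority vote over SVM, random forest, network and KNN
  (configurable, e.g. the naive-Bayes + network pair): `apVote` and
  `noapVote` count member predictions and the result is apathy iff
  `apVote ≥ noapVote`, i.e. ties break toward apathy (the clinically
  conservative direction — a tie flags the subject for follow-up). Members
  already fitted elsewhere can be reused (`prefitted=True`), which the
  sweep exploits.

## Evaluation protocol

A single stratified split with exact per-class counts — 48/102 train,
8/20 test, shuffled by a seed — mirrors a one-shot study design; no
cross-validation by default. Rates are fractions of the **whole test
set**, not of their class: with this denominator the four rates sum to 1,
total accuracy = Apathy-C + Non-Apathy-C equals the overall fraction
correct, and the ceiling of any constant predictor equals its class's test
share (20/28 ≈ 71.4 % for non-apathy). Per-class recall can always be
recovered by dividing by the class share.

`run_sweep` evaluates every channel × threshold × model cell on the same
split (default 4 × 18 × 7 = 504 records); channel planes are extracted once
per channel, and the ensemble reuses the member models fitted for the same
cell. `grid_comparison` repeats the sweep per separation grid. Everything
is reproducible bit-for-bit from (dataset seed, split seed, model seed).

No class weighting or resampling is applied to the 48/102 imbalance; the
resulting majority-class bias of the weaker models (e.g. the linear SVM
sitting at the 71.4 % ceiling) is part of the behaviour being studied.

## Synthetic generator

The generator emulates the *structure* the feature extractor assumes, not
radar physics. Each image is an intensity field in [0, 1] on a 256×256
canvas (rows = velocity, columns = time; zero-velocity baseline at 3/4
height), rendered through the jet colormap (`bytes=True`, so rendering is
exact and bit-reproducible):

* **Torso trace** — a Gaussian ridge oscillating at the stride frequency
  (default 2 cycles per image) around `torso_velocity_mean` (default 20
  rows) above the baseline; its brightness saturates with velocity so a
  stationary subject leaves no trace.
* **Limb bursts** — one elongated Gaussian blob per step (default
  `n_steps = 4`, one per time strip of the 4×4 grid) reaching
  `limb_burst_amplitude` (default 60 rows) toward high velocities, width
  `limb_burst_width` (default 8 columns). The burst's integrated intensity
  scales with its amplitude.
* **Noise** — additive uniform noise, default amplitude 0.05.
* **Per-subject vigor** — one multiplicative factor per walk,
  `max(0, 1 + 0.15·N(0,1))`, applied to torso velocity and burst
  amplitude. This is what makes subjects of one class differ by more than
  pixel noise; without it the classes are deterministically separated and
  every classifier saturates, which no field study resembles.
* **Class effect** — apathy scales torso velocity and burst amplitude by
  0.7 (slower, lower-amplitude gait). The factor is configurable; at 1.0
  the two class distributions are identical (verified by a permutation
  test on total image intensity), so the separation→accuracy relationship
  can be explored.

Questionnaire totals are drawn per class from discretized truncated
normals — apathy N(22, 3²) on [16, 42], non-apathy N(9, 3²) on [0, 15] —
then allocated to the 14 items one point at a time respecting the
per-item maximum of 3. The questionnaire-derived label therefore always
equals the stored label, and the dataset container re-validates this
invariant on construction.

Default cohort: 56 apathy + 122 non-apathy = 178 samples, exactly
supporting the 48/102/8/20 split.

### What the generator does and does not show

Passing tests on synthetic data demonstrate that the *pipeline* is correct
(feature arithmetic, contracts, determinism, protocol identities) and that
the classifiers can exploit a gait-vigor class difference of realistic
effect size. They do **not** demonstrate clinical accuracy on real radar
data: real spectrograms have STFT speckle, range-dependent gain, clothing
and gait-style variation, and a weaker, noisier link between apathy and
gait. Two known divergences in particular:

* In the jet rendering used here the blue channel remains class-informative
  through its *background* (the background area is the complement of the
  signal area), whereas on real data the blue channel is reported to carry
  the least usable signal. The qualitative ordering of channels on
  synthetic sweeps should not be over-read.
* Synthetic class separation at the default settings is stronger than the
  ~75 % regime reported on real cohorts; headline synthetic accuracies are
  an analog, not a reproduction.

## Degenerate inputs and tie-breaks

* All-zero intensity (all sources off) renders the colormap's zero colour
  everywhere; thresholds above the image maximum give all-zero features.
* Burst width below half a pixel is clamped to 0.5 columns to keep the
  Gaussian well-defined; vigor draws are clamped at 0.
* Grid larger than the mask, unknown channels/labels/models, single-class
  training sets, unfitted predictions, and unknown config keys all raise
  `ValueError`/`RuntimeError` naming the offending input.
* KNN cannot tie (odd k); the ensemble ties toward apathy; the network
  maps confidence exactly 0.5 to non-apathy (strict inequality).

## Problem sizes used by the test suite

The suite exercises the full 178-image cohort at 256×256 for the sweep and
network checks (the complete 504-record sweep runs in a few seconds) and a
24-image 64×64 cohort for pipeline/CLI round trips; property tests use
masks up to 20×20 against brute-force oracles.
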