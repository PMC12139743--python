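# Methods

## The encoding model

For each participant, brain area (DLPFC or pSTC) and condition (speech
or music blocks), the HFB response is modelled as a linear function of
time-lagged facial-emotion features:

y(t) = Σ_f Σ_l β[f, l] · x_f(t − τ_l) + ε(t),   τ ∈ {0, 0.5, 1} s,

where x_f are the 48 feature timecourses on a 2 Hz grid (bin-averaged
from per-frame scores; the maximum over detected faces is taken per
frame, and frames without faces score 0), and y is the baseline-z-scored
HFB amplitude averaged into 500 ms bins. Lagged regressors are
zero-padded at block starts: blocks are separate epochs and are never
lag-convolved across their boundaries. Contacts within an area are
concatenated — the design is replicated per contact and the responses
stacked — so one weight vector is fitted jointly per
(participant, area, condition).

β̂ is the closed-form ridge solution on column-centred X and centred y
(weights exclude the intercept; features keep their native [0, 1]
scale, since a shared regularisation strength is only meaningful if
weight scales stay comparable). Performance is the Pearson r between
measured and predicted response on held-out folds, averaged over 5
folds. Folds are contiguous block groups: the stimulus blocks are
round-robined into five folds and every row of a block (across all
concatenated contacts) stays in its fold, respecting temporal
autocorrelation. One λ, selected from 20 log-spaced values in
[10, 10⁴] by maximising the unweighted mean CV accuracy across all
datasets, is shared by every dataset.

Implementation note: CV at a fixed λ is computed from per-block Gram
contributions (training-fold Gram = total − held-out, with
training-mean centring applied analytically). This is algebraically
identical to refitting each fold from scratch — the equality is
asserted in the test suite — and makes the 200-dataset × 199-shuffle
calibration run tractable on one CPU.

## Inference

Group-level tests on per-participant mean r are classical t-tests:
one-sample against 0, paired for speech vs music, and two-sample
Student (equal-variance) for childhood vs post-childhood; the voice
effect is the per-participant speech-minus-music difference, contrasted
between groups with the same unpaired t. Ages below 13 are childhood,
13 and above post-childhood; ages in (10, 13) fall outside both study
ranges and are rejected.

Single-participant significance uses a temporal-shuffle permutation
test: the 2 Hz feature bins are permuted uniformly at random across the
condition's blocks, jointly over all 48 features (cross-feature
structure and every marginal are preserved exactly), the design is
rebuilt and the blocked CV re-run, 5000 times by default. The
two-tailed p is (#{|null| ≥ |observed|} + 1)/(n_perm + 1); the +1
correction keeps p strictly positive where a raw proportion could be 0.
A block-wise circular-shift mode is available as a stricter null that
preserves within-block autocorrelation; the uniform shuffle is the
default because it matches the plain "shuffle in time" procedure. A
group-level variant (features shuffled independently per participant,
the across-participant mean accuracy collected per iteration) serves
small-group inference such as the four-child pSTC sample. Under
the null (response independent of features) the test is exactly
calibrated: for Gaussian held-out responses the distribution of the CV
r statistic is invariant to the feature permutation, and the test suite
verifies uniformity of p empirically.

## Weight analysis

Each fold contributes 144 coefficients (48 features × 3 lags). Pooling
takes |β| averaged over the 5 folds and then over the 3 lags (a max
over lags is available as an option), yielding one non-negative
magnitude per feature; the absolute value deliberately ignores the sign
of the feature-to-HFB mapping. Only participants whose encoding is
individually significant (permutation p < α = 0.05) enter the age
analysis. Per feature, the pooled magnitude is Pearson-correlated with
age (two-sided p, uncorrected) and features are ranked by r descending;
zero-variance features have undefined r and are excluded with a
warning. The complex (guilt, embarrassment, pride, envy) and basic
(joy, sadness, fear, anger, disgust, surprise) aggregates are computed
by averaging the pooled magnitudes within each class first and then
correlating with age — not by averaging per-feature correlations, which
is a different quantity. A five-emotion complex set including interest
is available as a configuration option.

A caveat worth knowing when reading synthetic-cohort results: because
pooling uses absolute values, the noise floor of |β̂| grows with the
overall SNR of a dataset. In a cohort whose total signal strength
increases with age, even features with age-constant true weights
inherit a weak positive weight–age trend. The complex/basic *ranking*
is robust to this shared offset; the basic-aggregate correlation in a
strongly age-graded synthetic cohort is not a null and should not be
read as one.

## The synthetic cohort generator

The generator emulates the study conditions so that every downstream
stage has a known ground truth:

* **Schedule** — 13 interleaved 30 s blocks alternating music/speech
  (7 music + 6 speech), 2 s gaps covering the −0.2 s baseline window;
  the fifth music block is flagged feature-absent and contributes no
  design rows (its epochs are still extracted, only flagged).
* **Features** — each of the 48 features is white noise smoothed with a
  Gaussian kernel (SD 2 s by default), standardised and mapped to
  0.5 + 0.25z clipped to [0, 1]: a bounded, temporally smooth process.
  Only boundedness and smoothness matter downstream; the generator does
  not emulate the heavy zero-inflation or cross-feature correlation of
  real face-model scores.
* **True weights** — sparse and heavy-tailed: on average 1 feature in 6
  carries signal, with exponentially distributed per-feature effect
  scales (scale 0.3) and random signs across lags. Dense i.i.d. weights
  would make the between-feature variance of true pooled magnitudes
  small relative to estimation noise and weight-profile recovery
  structurally impossible at realistic SNR; sparse selectivity is also
  what encoding-model studies typically report.
* **Response** — the forward model above plus i.i.d. Gaussian noise on
  the 2 Hz grid (default SD 2.0 z-units, giving single-participant
  accuracies around 0.1–0.2, the observed magnitude). Where a target
  signal-to-noise level is needed, the noise SD is calibrated to a
  population R² on the realised design; R² ≈ 0.12 reproduces observed
  accuracies of ≈ 0.2. Note that held-out r sits well below √R²
  because 144 collinear lagged weights are estimated from 576 training
  bins.
* **Cohort structure** — 11 children (ages 5–10; 8 with DLPFC, 4 with
  pSTC coverage) and 31 post-childhood participants (13–55; 13 DLPFC,
  25 pSTC), at least four contacts per covered area. Per participant,
  complex-emotion weights equal the base weights plus
  `complex_age_slope × (age − min age)` (default slope 0.01/year in the
  analysis drivers); childhood-DLPFC weights are zeroed, building in a
  null with known truth; music-block weights are scaled by a
  `voice_gain` factor (0.85 in the drivers) to emulate the voice effect.
* **Raw signals** — for testing the preprocessing chain end-to-end, a
  contact's recording is synthesized as carrier-band (110–140 Hz) noise
  whose own envelope is normalised flat, amplitude-modulated by the
  squared target envelope (squaring inverts the chain's square-root
  transform), plus a 50 Hz line component and 1/f background noise, at
  1000 Hz (the acquisition rate is a free choice; it must exceed
  2 × 140 Hz and the 400 Hz target). The default modulation depth is
  0.5 around a baseline level of 1; for z-scored targets spanning ±4 a
  depth of ~0.15 avoids clipping the envelope at zero.

What passing tests on this cohort do *not* show: robustness to
epileptiform artifacts, imperfect electrode localisation, non-Gaussian
HFB noise, inter-subject stimulus timing differences, or correlated
feature errors — none of which the generator emulates.

## Numerical and procedural choices

* Zero-phase (forward–backward) filtering everywhere, so envelope
  latencies are not shifted; the notch is a narrow IIR (Q ≈ 30) at the
  50 Hz fundamental only.
* Downsampling by polyphase anti-aliased resampling with
  linear-extension padding — constant-extension padding leaks a startup
  transient into the 0.2 s baseline window.
* Baseline statistics are computed after downsampling and the square
  root, i.e. the baseline undergoes exactly the transforms of the epoch
  it normalises. A baseline whose SD is below 1e−4 of its mean is
  treated as degenerate (that level is filter ripple, and z-scoring
  against it would only amplify ripple).
* Bad channels are an explicit exclusion list (`status` column of the
  channels TSV), replacing visual artifact inspection; they are
  excluded from the common average but still re-referenced by it.
* Zero-variance held-out folds score r = 0 (with a warning) so group
  statistics stay total; λ-grid ties resolve to the smaller λ.
* The per-participant inclusion p for the weight stage defaults to 199
  shuffles in the pipeline driver (floor 1/200, enough to resolve the
  α = 0.05 threshold); the single-participant test default remains
  5000.
* All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning; identical config + seed gives
  bit-identical outputs.

## Problem sizes

The test suite and the acceptance script use the study-scale design
(12 feature blocks × 60 bins = 720 rows × 144 columns per condition,
4–8 contacts per area): permutation calibration uses 200 null datasets
at 199 shuffles each (100 in the acceptance script), recovery and
cohort checks use 20 seeds, and the analysis drivers use 499 shuffles
per participant instead of 5000.

## Known limitations

* The interpretation of "contacts concatenated" as design replication
  (one shared weight vector per area) is the main ambiguity of the
  procedure; averaging contacts instead is not implemented, only
  row-stacking.
* Whether per-fold r should be Fisher-z averaged is unspecified; the
  plain mean is used.
* The permutation and CV machinery assume equal-length blocks on the
  2 Hz grid.
* The BrainVision ingest path for real recordings is not included; the
  raw binary + JSON sidecar format is the only raw input.
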