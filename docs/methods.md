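# Methods

`midecode` re-implements, as a tested library, a motor-imagery EEG decoding
analysis: seven task conditions (move, imagine and observe foot or hand
movement, plus rest) are classified pairwise from 1 s EEG segments using
either band-power (FFT) features or directed-connectivity (ffDTF) features,
over four montage densities, inside a three-layer nested cross-validation
with greedy feature subset selection, and the resulting correct counts are
tested against a maximum-chance criterion.  Because no public recordings of
such a study exist, the package ships a synthetic study generator that
reproduces the statistical structure the analysis assumes; everything
downstream is exercised end-to-end on generated data.

## Study schema and synthetic data

A study consists of continuous Cz-referenced recordings at 250 Hz, by default
22 control recordings and 14 patient recordings (7 patients, four of whom
return for repeat sessions, distributed 2/4/2/3/1/1/1).  Each recording
presents the 7 conditions 25 times each in a seeded random intermixed order;
a trial is a 6 s epoch from the pacing-tone onset, and trials are separated
by 1 s gaps.

The generator's signal model is deliberately the simplest one that exposes
band-power class structure:

* **Background**: per-channel Gaussian noise shaped to a 1/f^α spectrum
  (α = 1 by default), unit variance.
* **Sensorimotor rhythms**: narrow-band oscillators at μ (10 ± 1 Hz) and β
  (22 ± 3 Hz) over two channel groups — a *hand* area around C3/C4 and a
  *foot* area around the vertex (radius 0.27 on the unit head).  Amplitudes
  are 2.0 (μ) and 1.2 (β) relative to the unit background so the rhythm
  dominates its band at the generating channels; each trial draws a random
  phase, a frequency jitter and a ±10 % log-normal amplitude jitter.
* **Condition effects**: a multiplicative power factor per
  (condition, group, band).  The defaults encode event-related
  desynchronization ordered movement > imagery > none: moving the foot
  suppresses μ power to 0.35 over the foot area (0.6 over the hand area, β to
  0.5/0.7), moving the hand mirrors this, both imagery conditions suppress μ
  to 0.7 over *both* areas identically — making the two imagery conditions
  mutually indistinguishable while each remains separable from rest — and the
  observation conditions and rest carry the unmodulated baseline, so the
  OF–OH pair is a designed negative control sitting at chance.  The paper the
  protocol emulates reports no effect sizes, so these factors are free,
  fixed design parameters of the generator, not estimates.
* **Patient profile**: the reactive μ rhythm is shifted down by 2 Hz
  (10 → 8 Hz), emulating post-injury cortical slowing.  β is left in place.
* **Volume conduction**: latent per-channel sources are mixed by a
  row-normalized distance-decaying matrix (length scale 0.18); this spreads
  the rhythms over neighbouring channels without a head model.
* **Optional components**: common-mode 50 Hz line noise and latent sources
  with known MVAR coupling (for connectivity ground-truth tests).

What the generator does *not* emulate: realistic forward-model topographies,
eye-blink/EMG artifacts, inter-subject variability beyond the seed,
non-stationarity within a session, and electrode noise correlations.  Tests
passing on this data therefore validate the *pipeline mechanics and
statistics* (segmentation accounting, leakage-free folding, normalizations,
chance calibration, recovery of planted effects), not clinical decoding
performance.

The synthetic net layout places the 19 standard 10-20 electrodes first and
fills the scalp with a deterministic golden-angle spiral; nets larger than
197 channels put the excess on an outer face/neck ring.  Because Cz is the
recording reference it is not a data channel; the 19-label low-density set
substitutes Oz for Cz (a Cz channel would be identically zero and make MVAR
covariances singular).

## Preparation

A causal 4th-order Butterworth high-pass at 1 Hz and a quality-30 IIR notch
at 50 Hz are applied to the continuous record (the emulated protocol names
only "IIR from 1 Hz" and a 50 Hz notch; the concrete designs are this
package's choice).  Epochs of 6 s are cut from each trial onset with no
baseline window and no artifact rejection, then split into six consecutive,
non-overlapping 1 s sub-segments (250 samples) that inherit the trial's
condition and id — 150 segments per condition at 25 trials.  Montages reduce
the channel axis to one of: LD-SM (C3, C4), LD-whole (19 ten-twenty
positions), HD-SM (27 channels nearest the central strip) and HD-whole
(all scalp channels; 197 on the 256-channel net after excluding the
face/neck ring).  The HD channel lists are declared approximations, shipped
as editable text resources and re-derivable for any net size.

## Features

**FFT.** Per segment and channel, the one-sided magnitude-squared FFT at
integer frequencies (1 Hz bins; the 250-sample segment needs no taper or
detrend beyond the 1 Hz high-pass, so a rectangular window is used and the
Parseval identity holds exactly).  Bins 1–48 Hz are averaged into 13 bands:
2 Hz bands up to 20 Hz, then 21–30, 31–40 and 41–48 Hz — boundary bins belong
to the lower band so the bands partition the grid.  Features are raw power by
default (a log-power switch exists), flattened channel-major: M × 13 values.

**ffDTF.** Per segment, an MVAR model x(t) = Σₖ Aₖ x(t−k) + e(t) is fitted
with the Vieira–Morf lattice recursion (forward/backward prediction-error
partial correlations with unbiased covariance normalization); an OLS fit is
kept as an independent cross-check for small M.  The spectral transfer
matrix H(f) = (I − Σₖ Aₖ e^{−i2πfk/fs})⁻¹ is evaluated at 1–48 Hz, and the
full-frequency Directed Transfer Function

    η²ᵢⱼ(f) = |Hᵢⱼ(f)|² / Σ_{f'} Σ_m |Hᵢₘ(f')|²

normalizes inflow to each sink over the whole frequency interval, so per sink
Σ_f Σ_j η²ᵢⱼ(f) = 1 (enforced to 10⁻⁹ in tests).  The squared-magnitude form
is the default; a magnitude variant is switchable.  Band-averaged values for
every ordered channel pair *including self-flows* give M·M·13 features —
self-flows are required to reproduce the full 197 × 197 × 13 vector length of
the emulated analysis.

Model orders per montage are fixed constants {LD-SM: 50, LD-whole: 12,
HD-SM: 9, HD-whole: 1}.  The guideline N/(M·p) > 1 at N = 250 yields the
maximum orders 124/13/9/1; the configured LD-whole order (12) and the
deliberately high LD-SM order (50) follow the emulated analysis rather than
the rule, and `max_model_order` implements the rule itself.  When a montage
is adapted to a smaller net, its order is re-capped by the rule.

## Classification

Pairwise condition classification uses a soft-margin linear SVM.  The
emulated analysis used MATLAB's `svmtrain` (2-norm soft margin, quadratic
programming, which autoscales features by default); this package uses
scikit-learn's libsvm-based `SVC(kernel="linear")` with C = 1 and per-fold
feature standardization.  The hinge (1-norm) penalty differs from the 2-norm
variant only in how margin violations are weighted; with standardized
features and C = 1 the decision boundaries are practically indistinguishable,
and C is exposed in `ClassifierParams`.

The nested design: an outer 3-fold split estimates generalization; within
each outer training set a middle 5-fold loop runs feature selection five
times; candidate feature sets are scored by inner 5-fold cross-validation on
the middle training set.  All folds assign whole trials (six sub-segments
travel together), stratified per condition with trial counts differing by at
most one (25 trials split 9/8/8 across three folds), and every plan is
audited for trial leakage at run time.

Feature selection per middle run: features are ranked by ascending
pooled-variance two-sample t-test p-value (zero-variance features get p := 1
and rank last; ties keep index order).  Greedy forward selection starts from
the top-ranked feature and walks the ranking; a candidate is kept iff its
pooled inner-CV accuracy is ≥ the best accuracy of all previously accepted
vectors, and — while the best sensitivity so far is below 0.75 — it does not
reduce sensitivity, and — while the best specificity so far is below 0.5 —
it strictly improves specificity (the source text's constraint wording is
self-contradictory; this monotone reading is a documented interpretation).
Acceptance comparisons are made on integer correct counts, never on floats.
The walk stops when candidates are exhausted, 30 features are accepted, or
the consecutive-rejection streak exceeds max(⌈0.10·F⌉, 100).  Note that
accepting ties means harmless uninformative features can accumulate toward
the 30-feature cap; the subsequent consensus vote is what prunes them, since
randomly accepted features rarely recur across runs.

Consensus over the five runs keeps features selected in ≥ 2 runs (falling
back to ≥ 1 if empty); if the consensus exceeds the mean run length N̄, the
31 most-selected features are kept, ties broken by better t-test rank (the
best rank a feature achieved across the five runs — the tie-break source was
an open choice).  The consensus vector trains an SVM on the full outer
training set and is scored on the outer test fold; correct counts pool over
the three outer folds, so N equals the total segment count (300 for a
25-trial pair) and H₀/N is the reported accuracy.  Sensitivity and
specificity are the within-condition accuracies of the pair's first and
second member.

## Chance statistics

With a pooled test set of N segments and maximum chance criterion HC (the
larger class size), a correct count H₀ is above chance when

    z = (H₀ − HC) / sqrt(HC (N − HC) / N)

exceeds the standard-normal critical value.  Two-sided critical values are
the default: the balanced N = 300 case then gives a critical count of 167
(55.67 %), which is the internally consistent reading of the emulated
analysis.  Bonferroni correction divides α by the number of tests (14 for
7 comparisons × 2 feature kinds → α = 0.0036).  Arbitrary imbalance is
supported; exact-binomial or permutation baselines are deliberately out of
scope (the normal approximation's false-positive rate is checked by
simulation in the tests).

One caveat is worth stating explicitly.  The criterion counts *segments*, but
the six sub-segments of a trial are not independent: they share the trial's
oscillator phase and amplitude, and a trained classifier tends to judge them
together.  Under the null the pooled count therefore varies like ~50 trial
outcomes rather than 300 segment outcomes, which makes the segment-level
critical count slightly anti-conservative — in null simulations the pooled
count occasionally lands a few segments above 167 (we observed up to 170 of
300 across twenty null studies) while never approaching the trial-level
critical count (192 of 300, i.e. 32 of 50 trials).  The tests document both
bounds; users comparing single recordings against the 167 cut-off should
treat marginal exceedances with caution.

## Experiment grid and summaries

The full grid enumerates recordings × 7 comparisons × 4 montages per feature
kind (1008 cells per kind for 36 recordings) with a deterministic derived
seed per cell; failures are logged per cell without aborting, and runs are
resumable by cell id.  Summaries are pure functions of the long results
table: group-wise mean accuracies, counts of recordings with accuracy
strictly above a threshold (default 0.75), within-class accuracy
distributions, and the proportion of recordings selecting each
(channel-or-pair × band) feature.  Patients' repeat sessions count as
separate recordings, with a first-session-only filter available.

## Problem sizes and numerical choices

The test suite and examples run on a desk-scale profile: 32–64 channel nets
(HD-whole then simply keeps all channels), LD-SM/FFT grids, and full
25-trial recordings where counts matter (N = 300).  The 197-channel profile
works but is slow, since ffDTF on HD-whole means fitting a 197-channel MVAR
per segment.  Statistical tests fix their seeds; Monte-Carlo tolerances are
stated per test (e.g. planted μ-power ratios recovered within 10 % at
25 trials; AR(1) coefficients within 0.02 at n = 10,000; null calibration in
≥ 19 of 20 seeds).  Degenerate inputs are errors, not warnings: duplicated
channels make the lattice's Cholesky step fail (reported with the lattice
stage and segment id), montages naming absent channels report the label, and
events extending past the data report the trial id.

## Known limitations

* The generator's mixing is a 2-D distance kernel, not a volume-conduction
  forward model; connectivity estimated on mixed channels reflects the
  mixing as much as the planted coupling, which is why parameter-recovery
  tests run on unmixed latent sources.
* Consensus tie-breaking and the greedy constraint reading are documented
  interpretations of an ambiguous source procedure.
* The semi-parametric repeated-measures ANOVA-type statistic sometimes used
  on such result tables is intentionally not reimplemented; the long-format
  results CSV is the interface to external statistics packages.
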