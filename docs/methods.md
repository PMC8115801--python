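# Methods

## The detection problem

A participant performs an auditory target-detection (oddball) task while
EEG is recorded; at unpredictable moments a thought probe asks whether
they were *on task* or *mind wandering*.  Each probe labels the block it
ends.  The goal is a binary classifier of attentional state from
event-related potential (ERP) features of the trials preceding each
probe — evaluated both *person-dependently* (train and test within one
subject) and *person-independently* (test on a subject the model has
never seen, the setting that matters for deployment).

## Synthetic sessions

Real recordings of this protocol are not bundled; the package ships a
generator that emulates the paradigm's design quantities exactly and its
physiology parametrically.

**Design (fixed by the paradigm).** 14 subjects; 25 blocks per session;
block durations uniform on 45–75 s; 1500 tones per session in
exact-proportion mode (1200 standard / 300 target, apportioned to blocks
by duration with largest-remainder rounding) or i.i.d. Bernoulli draws
(p_target = 0.2) in `bernoulli` mode; 200 ms tones with 800–1200 ms
uniform inter-trial jitter; epochs −1000…+2000 ms at 512 Hz (1536
samples); six electrodes (FC1, FCz, FC2, P1, Pz, P2).  A montage with
extra zero-gain channels can be configured.

**Attention states.** Each subject's mind-wandering rate is drawn from a
Beta distribution moment-matched to mean 0.55 and SD 0.198 (the SD
implied by a reported standard error of 5.3 % over 14 subjects),
truncated to [0.20, 0.88] by redraw.  Block states are independent
Bernoulli draws at that rate.  With these tails, two or three subjects
per cohort typically fail the downstream N < 5 minority rule — the
exclusion path is exercised routinely, not exceptionally.

**ERP components.** N1 (negative, latency 100 ms, width σ = 20 ms, on
the fronto-central sites) and P3 (positive, 500 ms, σ = 80 ms, parietal
sites), with a 2×2 amplitude table over state × tone.  Defaults:
N1 −5 µV standard / −8 µV target, P3 +6/+12 µV, and mind-wandering
amplitudes scaled by (1 − a) with attenuation a = 0.3.  Amplitudes are
defined at the virtual electrode obtained by averaging the component's
analysis sites (those sites carry unit topography gain).

*Band-limited rendering.*  A naive Gaussian bump is **not** preserved by
the downstream 1–15 Hz zero-phase filter: the 1 Hz high-pass removes
~10 % of a σ = 20 ms pulse's peak and ~42 % of a σ = 80 ms pulse's
(measured numerically on this grid).  Component waveforms are therefore
pre-conditioned: the Gaussian is passed repeatedly (8 iterations)
through the analysis chain (4th-order Butterworth band-pass applied
forward–backward, then −200…0 ms baseline subtraction), renormalising
the extremum near the nominal latency each pass.  The fixed-point shape
changes by <1.4 % under one further application of the chain, so
noiseless cohorts reproduce configured amplitudes to within 2 % after
feature extraction.  `erp_waveform` still exposes the analytic Gaussian
(`band_limited=False`) for waveform-level reasoning.

**Noise and variability.** Per trial and channel: 1/f noise (spectral
shaping of white noise by f^(−β/2), β = 1, analytically normalised to
unit variance) scaled to 4 µV, plus 4 µV white noise — a few µV of
residual single-trial amplitude, typical after a 1–15 Hz pass on cleaned
EEG.  Multiplicative Gaussian trial jitter (σ = 0.3) and per-subject
component gains (σ = 0.2, floored at 0.2) add within- and
between-subject amplitude variability.  Artifacts are Bernoulli flags
(p = 0.05) with no waveform corruption — only the exclusion logic
consumes them.  Target-tone reaction times are Gaussian (means 511 ms on
task / 535 ms mind wandering, trial SD 60 ms, subject offset SD 40 ms);
they feed only the behavioural t-test.

**What the generator does not emulate.** Volume conduction and realistic
topographies, ocular/muscular artifact waveforms, the acquisition chain
(1024 Hz digitisation, notch, ICA, re-referencing), non-stationary
attention dynamics (block states are exchangeable), and latency jitter
of the components.  Passing tests therefore establish the *pipeline's*
correctness and calibration — not that real EEG supports any particular
accuracy.

## Feature extraction

Per block: the last up-to-10 artifact-free pre-probe trials; standard
tones only (targets are too rare per block for stable estimates);
zero-phase 4th-order Butterworth 1–15 Hz band-pass with reflection
padding per epoch; baseline to the −200…0 ms mean; channels of interest
averaged first, then the N1 minimum over 80–120 ms and the P3 maximum
over 400–600 ms taken per trial (window endpoints inclusive, times
mapped to nearest samples).  Features are the across-trial mean and
sample (n−1) SD of each peak measure — per-trial peaks first, then
mean/SD, not the peak of the trial average.  Blocks with fewer than two
usable trials are dropped with a logged warning (the SD is undefined).

Normalization subtracts, per subject and per feature, the mean over that
subject's on-task blocks.  As published, this uses the subject's own
labels — including the held-out subject in person-independent
evaluation.  That is a mild label leakage: on null (zero-effect)
cohorts it lifts mean LOSO AUC from 0.50 to ≈0.52, because the on-task
rows are centred on their own sample mean while mind-wandering rows are
not.  A `normalization="train_stats"` switch instead centres the
held-out subject on the training cohort's pooled on-task mean.

## Balancing and classifiers

SMOTE with k = 5 Euclidean nearest minority neighbours (k reduced with a
warning when the minority has ≤ k rows); parents cycle deterministically
over minority rows, the neighbour and γ are fresh draws per synthetic
point; applied to training folds only.  Subjects with fewer than 5
minority-class blocks are excluded entirely.  Classifiers: RBF-kernel
SVM (C = 1, γ = 1/(n_features·Var X)) and L2 logistic regression
(C = 1) — era-typical library defaults, surfaced in `ModelSpec`; no
hyperparameter search by design.  Decision scores are the SVM margin and
the logistic linear predictor (AUC uses these continuous values; hard
predictions threshold at 0).

## Evaluation

Person-dependent: shuffled 5-fold CV over one subject's blocks,
stratified when each class has ≥ 5 rows; metrics are computed once on
the out-of-fold scores pooled across folds (per-fold AUC on 5 rows is
too unstable); the fold-averaged accuracy is also recorded.  Aggregation
over subjects reports mean ± SE.  Person-independent: leave-one-subject-
out with SMOTE on the pooled training rows per iteration; aggregation
reports mean ± SD.  Mind wandering is the positive class throughout;
confusion matrices are normalized per actual class (columns sum to 1).
MCC is defined 0 when a marginal is empty.  Single-feature ablation
reruns the LOSO evaluation restricted to each feature in turn.

The 2×2 attention × tone ANOVA treats the 4n per-subject cell means as
independent observations (effect df 1, error df 4n − 4, i.e. F(1, 52)
at n = 14), matching the reported degrees-of-freedom structure; a true
within-subject variant (error df n − 1) is available via
`within_subject=True`.  Sums of squares are computed directly for the
balanced layout and are verified against an OLS ANOVA in the tests.

## Numerical and reproducibility choices

One global seed fans out to per-stage child seeds (CRC-keyed XOR,
< 2³¹), so stages rerun in isolation reproduce a full run bit-for-bit.
Feature CSVs are written at %.17g and parsed in round-trip mode, so
write∘read is the identity on float64.  Monte-Carlo studies (null
calibration, attenuation sweeps) use the generator's `short_blocks()`
preset (~13-trial blocks in Bernoulli mode): block features depend only
on the last ten pre-probe trials, so the feature distribution is
unchanged while simulation cost drops several-fold; structural checks
(tone counts, 250 pre-probe trials) always run at full session size.

## Known limitations

Simulated effect sizes are optimistic relative to real recordings — at
the default attenuation the decoders approach ceiling, whereas real
standard-tone ERP effects of attention are small; treat the synthetic
benchmark as a correctness/calibration harness, not a performance
forecast.  The exact-proportion tone mode fixes session-level counts,
slightly decoupling block duration from trial count.  Bernoulli block
states ignore the temporal autocorrelation of attention.  The default
pooled training-set SMOTE in LOSO mixes subjects when interpolating;
``smote_scope="per_subject"`` balances each training subject separately
instead.
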