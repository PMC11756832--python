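# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and the limits of what the package's passing tests
demonstrate.

## Outcome definition

The K-FRAIL questionnaire scores five binary items. The categorization is a
pure function of the score — 0 robust, 1–2 prefrail, ≥3 frail — and the
binary target pools prefrail with frail, so `label = 1 ⇔ score ≥ 1`. All
cohort records enforce `score = Σ items` and the category/label consistency
as dataclass invariants.

## Synthetic cohort

The generator emulates the screening cohort the analysis was designed for:
community-dwelling adults aged 50+, 51.2% positive prevalence by default
(65/127), positive participants markedly older. Class-conditional defaults:

| parameter | robust | prefrail/frail |
|---|---|---|
| age mean (SD), years | 64.9 (9.26) | 73.4 (10.84) |
| female fraction | 0.274 | 0.40 |

Ages are truncated normals on [50, 95]. Truncation biases a naive draw
(≈ +1 year for the robust class), so the underlying location is solved by
root finding so the *truncated* mean hits the target; at n = 2000 the class
means land within sampling error of the targets. The prefrail share within
the positive class (unreported in the source cohort) defaults to 0.7.
Within a category the item pattern is drawn uniformly given the score.

## Speech synthesis

Recordings are rendered with a source-filter model: a glottal impulse train
at a sex-dependent base F0 (male 120 Hz, female 210 Hz) with a slow random
F0 contour, per-cycle jitter (period) and shimmer (amplitude) perturbations,
filtered by three cascaded second-order formant resonators (500/1500/2500 Hz),
gated into voiced bursts separated by silent pauses, with low-level
aspiration noise inside bursts, peak-normalized to 0.9. The resonator
cascade's passband gain is far below unity, so the voiced path is
renormalized before noise is mixed; otherwise the noise floor dominates and
destroys periodicity.

Severity scales linearly in the K-FRAIL score between a score-0 baseline and
a score-5 extreme: pause fraction 0.12 → 0.50, burst rate 3.8 → 1.8 /s,
jitter 0.008 → 0.05, shimmer 0.04 → 0.20, F0 spread 25 → 6 Hz. These effect
sizes are a design choice calibrated once so the acoustic signal is
learnable at cohort sizes around 200; they make the classes *more* separable
than clinical speech, which is why cross-validated AUCs on synthetic
cohorts saturate near 1. Passing recovery tests therefore demonstrate that
the pipeline recovers a planted acoustic signal and the expected model
ordering — not that the absolute published performance is reproduced.
Default clips are 10 s (config knob; desk-scale runs use 2–4 s); WAVs are
mono 16-bit PCM at 48 kHz. Not modelled: language content, phonetics, room
acoustics, background noise.

## Acoustic features

Clips are resampled to 16 kHz (configurable off) and framed at 25 ms / 10 ms
hop with a Hann window. Power spectra pass through a 64-band triangular mel
filterbank (HTK mel scale, 20 Hz–Nyquist), log with floor 1e−10, then an
orthonormal DCT-II; the first 20 coefficients are kept, *including*
coefficient 0, whose log-energy character gives the amplitude-invariance
property: scaling the waveform shifts column 0 additively and leaves
columns 1–19 unchanged. Deltas are local least-squares slopes over a
9-frame centered window (weights k/Σk², edges replicated); the second order
applies the operator twice. Feature matrices are T × 60.

Functionals (126 per clip, for the classical baselines): mean and SD of each
frame column (120), F0 mean/SD from an autocorrelation tracker (60–400 Hz
search band, parabolic peak interpolation, voicing = autocorrelation peak
≥ 0.3 on non-pause frames), voiced fraction, frame-RMS mean/SD, and pause
fraction from an adaptive RMS threshold (5% of the 95th percentile, floored
at 1e−5 so digital silence reports pause fraction 1). A fully silent clip
reports F0 statistics of 0 with voiced fraction 0.

## Model assemblies

The speech encoder is a post-norm transformer: input projection 60 → 64,
sinusoidal positions, 12 layers (4 heads, FFN 256, ReLU). Sequences longer
than 1,000 frames are split into non-overlapping chunks, each encoded and
mean-pooled over frames, then averaged across chunks — which makes the clip
embedding invariant to chunk order (property-tested). The demographic
module looks up the age decade (50s–90s, clamped with a warning below 50)
in a 5 × 2 table and sex in a 2 × 4 table, concatenated to 6 dims. Each
classifier is one ReLU hidden layer to two class scores, softmax to a
positive-class probability; widths 373 / 2889 / 466 were back-solved so the
full-size builds land on the published parameter budgets:

| assembly | total | speech encoder | classifier |
|---|---|---|---|
| SpeechAI | 628,705 | 603,712 (96.0%) | 24,993 |
| DemoAI | 26,021 | — | 26,003 |
| DemoSpeechAI | 637,750 | 603,712 | 34,020 |

The very wide DemoAI hidden layer (2,889 units over a 6-dim input) follows
the printed budget even though it is architecturally unusual. A `fast`
profile (2 layers, 32 dims, FFN 64, 500-frame chunks) preserves every shape
and probability contract for desk-scale runs; both profiles share all code
paths.

## Training

The numpy NN kernel implements exact analytic gradients (checked against
central finite differences to ~1e−9 relative error) and Adam (lr 1e−3,
β = 0.9/0.999). Everything is seeded; runs are bit-reproducible.

**Pretraining** is masked-frame reconstruction: 15% of frames per segment
replaced by a learned 60-dim mask token, MSE on the masked positions through
a linear head that is discarded afterwards. The corpus is synthetic,
severity-neutral, unlabeled (default 200 clips full scale, smaller in the
fast profile); a ~10% holdout tracks the loss trace, whose entry 0 is the
pre-training loss. The task choice is the canonical self-supervised speech
objective; nothing about the original pretraining task is published beyond
its existence.

**Fine-tuning** freezes the speech encoder absolutely — weights are compared
bit-for-bit before and after, and any drift raises — and trains the
classifier plus demographic tables by full-batch Adam on a class-balanced
training fold (majority undersampled without replacement). Because the
backbone is frozen, each clip is embedded once and cached; this is exactly
equivalent to end-to-end forward passes (property-tested to 1e−12). Early
stopping monitors cross-entropy on an inner stratified 80/20 split of the
training fold (patience 10, max 200 epochs) and restores the best epoch's
weights; the outer validation fold is never touched during training, which
is stricter than protocols that reuse the validation fold as the stopping
monitor. Optimizer settings, patience, and the inner split are package
defaults, not published facts.

## Evaluation protocol

Folds are stratified by shuffling within class and dealing to the currently
lightest folds, guaranteeing fold sizes within ±1 and per-fold class counts
within ±1 of the stratified ideal (property-tested over random cohorts).
AUC is delegated to scikit-learn's implementation and cross-checked in the
tests against an O(n²) all-pairs concordance oracle with ties counting one
half. Threshold metrics use 0.5 with *positive iff score ≥ threshold*.

Fold summaries use the normal approximation mean ± 1.96·SD/√k with the
sample SD — the convention that reproduces the published CI bounds exactly
(e.g., 85.6 ± 1.96·6.35/√5 → 80.03–91.17); with k = 5 folds the bounds can
exceed the metric's range and are reported as computed. Model comparisons
use the paired fold-level t-test on per-fold AUC differences, df = k−1,
two-sided p; all-zero differences return t = 0, p = 1, and a zero-SD
nonzero-mean vector returns p = 0 with a degeneracy flag. No multiplicity
correction is applied across the three pairwise comparisons.

The prevalence-shifted analysis keeps every negative and subsamples
positives to the largest count whose prevalence does not exceed the target
(floor semantics: 62 negatives at a 20% target give 15 positives, flagged
as inexact; 40 give exactly 10). A single subsample is high-variance, so
metrics are averaged over 20 seeded resamples.

Baselines run on the 126 functionals with fixed hyperparameters: logistic
regression (L2, C = 1, per-fold standardization), decision tree (depth 5),
random forest (100 trees), all seeded.

## Orchestration and problem sizes

`run_pipeline` derives every stage seed from the master seed by hashing, so
a config reruns to a byte-identical `metrics.json`; artifacts live under a
hash-named, timestamp-free run directory, and an evaluation-only mode
reloads per-fold classifier checkpoints instead of retraining. The
acceptance script and the recovery tests use the fast profile at n = 200
with 3-second clips and three seeds — sizes chosen so a full pass runs in a
few minutes on one CPU core while keeping each class comfortably above the
k = 5 stratification minimum.

## Known limitations

* The synthetic severity gradient is linear and purely prosodic; real
  frailty-related speech change is heterogeneous, so saturated synthetic
  AUCs say nothing about clinical effect sizes.
* The exact published parameter totals (e.g., 587,520) depend on an
  unpublished architecture; the full-size build targets the printed budgets
  within their brackets rather than digit-for-digit equality.
* Whether the 2-dim table maps to age and the 4-dim to sex is ambiguous in
  the source description; this package uses age → 2, sex → 4 as printed.
* The F0 tracker is a plain autocorrelation peak picker; octave errors at
  high jitter inflate the F0-SD functional. It feeds only the baselines.
* Cohort covariates beyond age and sex (education, cognition, depression
  scores) correlate with frailty in the modelled population but are neither
  generated nor used.
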