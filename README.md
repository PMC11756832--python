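# frailvoice

Vocal-biomarker screening for frailty in older adults, as a tested, fully
reproducible analysis pipeline.

Frailty — the geriatric syndrome of reduced physiological reserve — is
usually screened with questionnaires such as K-FRAIL (five binary items:
Fatigue, Resistance, Ambulation, Illnesses, Loss of weight; score 0 =
robust, 1–2 = prefrail, ≥3 = frail). Speech recorded during a free-speech
picture-description task carries prosodic and spectral correlates of
frailty, so a classifier over acoustic features can stand in for in-person
screening. This package implements that analysis end to end for a cohort
whose original recordings are not public: a seeded synthetic cohort
generator emulates the study population (class-conditional age/sex
distributions, K-FRAIL labels, and source-filter speech whose prosody
degrades with severity), and the modelling and evaluation layers run
unchanged on it.

## What it computes

Three binary classifiers (positive class = prefrail or frail):

* **SpeechAI** — a transformer encoder embeds the T × 60 frame matrix of
  MFCCs with first/second-order regression deltas (20 + 20 + 20 columns)
  into a fixed vector by chunked mean pooling; a one-hidden-layer classifier
  maps it to two class scores, `p(positive) = softmax(scores)[1]`.
* **DemoAI** — age decade (2-dim lookup) and sex (4-dim lookup) concatenated
  into a 6-vector, then the same classifier shape.
* **DemoSpeechAI** — both embeddings concatenated before the classifier.

The speech encoder is pretrained by masked-frame reconstruction
(self-supervised: 15% of frames replaced by a learned mask token, MSE on the
masked frames through a discarded linear head) on an unlabeled synthetic
corpus, then **frozen**: fine-tuning updates only the classifier and
demographic tables (≈4–5% of parameters in the speech-bearing assemblies).
At full size the speech encoder holds 603,712 of SpeechAI's 628,705
parameters — a 96% share; DemoAI totals 26,021; the combined model's
classifier 34,020.

Evaluation follows the study protocol: class-stratified ("balanced") 5-fold
cross-validation with majority-undersampled training folds; per-fold
accuracy, ROC AUC (all-pairs concordance, ties = 0.5), sensitivity,
specificity; fold summaries as mean ± 1.96·SD/√k (normal 95% CI); paired
fold-level t-tests (df = k−1) between models; a prevalence-shifted
sensitivity analysis at 20% positive prevalence; and classical baselines
(logistic regression, decision tree, random forest) on 126 per-clip
functionals (mean/SD of the 60 frame features, plus F0 mean/SD, voiced
fraction, RMS loudness mean/SD, pause fraction).

## Worked example

```python
from frailvoice import FrailtyClassifierModel, pipeline as pl
from frailvoice import evaluation as ev

cfg = pl.RunConfig(n=80, positive_prevalence=0.5, clip_duration=3.0,
                   ssl_corpus_size=24, ssl_epochs=4, seed=11)
model = FrailtyClassifierModel.from_config(cfg, kind="SpeechAI")
folds = ev.make_balanced_folds(model.dataset.labels, k=5,
                               seed=cfg.sub_seed("folds"))
res = model.fit(folds=folds)          # SSL pretrain + frozen-backbone CV
print(res.summary())

demo = FrailtyClassifierModel(model.dataset, kind="DemoAI",
                              profile="fast", seed=11).fit(folds=folds)
t = res.compare(demo)
print(f"paired AUC t-test: t{t.df}={t.t:.3f}, two-sided p={t.p:.4f}")
```

Output (seed 11):

```
SpeechAI: 5-fold cross-validation
  metric                   mean (95% CI)      min      max
  accuracy         98.75 (96.30-101.20)        93.75   100.00
  auc               1.00 (0.99-1.00)         0.98     1.00
  sensitivity       1.00 (1.00-1.00)         1.00     1.00
  specificity       0.97 (0.93-1.02)         0.88     1.00

paired AUC t-test: t4=5.016, two-sided p=0.0074
```

Read: on an 80-participant synthetic cohort whose class signal is
predominantly acoustic (more pausing, slower burst rate, more
jitter/shimmer at higher K-FRAIL scores), the speech-only model separates
the classes almost perfectly, while age+sex alone reaches AUC ≈ 0.70; the
paired fold-level test confirms the gap. The synthetic signal is cleaner
than real speech, so absolute numbers sit higher than one should expect on
clinical recordings — see `docs/methods.md` for what these runs do and do
not demonstrate. (The normal-approximation CI can exceed the metric range;
bounds are reported as computed.)

The same analysis scripts from a shell:

```bash
frailvoice run --seed 11 --profile fast --outdir runs
frailvoice report runs/run-<hash>
frailvoice params --profile conformance
```

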