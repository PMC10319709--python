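# Methods

This note records the modelling choices behind `notecast`, the reasoning
where the design was genuinely open, and what the synthetic experiments do
and do not establish.

## Problem and data model

The task is case-control discrimination of colorectal cancer (CRC) from
primary-care history alone, months before diagnosis.  A patient record is a
time-ordered list of consultations, each with zero or more ICPC codes and a
short free-text note.  The outcome is encoded as data: a consultation
carrying a code with prefix `D75`.  Labelling takes the *first* such
consultation as the case anchor; controls anchor at their last visit.

**Windows.**  Model input is restricted to `[anchor − 880 d, anchor − 150 d)`:
two years of history ending five months before the anchor.  The five-month
gap removes consultations in which the GP may already have been working up
the diagnosis (suspicion bias); without it the task degenerates into
reading back the GP's suspicion.  Calendar units are fixed — month = 30
days, year = 365 days — so boundaries are reproducible; the window is
half-open on the right and the boundary behaviour is pinned by tests.
Age is computed at the anchor (the only time point shared by both classes);
the inclusion gate is age > 30 plus at least one non-empty cleaned note or
tracked code in the window.

**Cleaning.**  Notes receive minimal syntactic cleaning only: characters
outside `a–z A–Z 0–9 + - / \` become spaces, runs of spaces collapse, and
the result is lowercased.  The rule is applied character-wise — token-wise
deletion would destroy every word touching a period.  Abbreviations,
digits and typos survive deliberately; in clinical shorthand they carry
signal.

## Text representation

Embeddings are trained **offline** on the cleaned notes of training-split
windows plus the notes of patients below the age gate (who never enter
prediction, so they enlarge the corpus without leakage).  Validation and
test notes never reach the vocabulary; a test asserts this by construction.

The trainer is skip-gram with negative sampling, written in vectorised
numpy: per epoch, tokens are re-subsampled with keep probability
`min(1, √(t/f))` *before* windowing (shrinking effective context
distances, as in the canonical method), the context radius per centre is
drawn uniformly from 1..window, negatives come from the unigram^(3/4)
distribution, and updates are applied over shuffled mini-batches of pairs
(size 256) with a linearly decaying learning rate (0.025 → 1e-4).
Mini-batching is a vectorisation choice; the per-pair objective and its
gradients are verified against central finite differences to < 1e-5
relative error, and signal recovery is tested on planted two-block
co-occurrence corpora.  Target vectors are uniform-initialised at scale
1/d; context vectors start at zero.  Default hyperparameters: d = 300,
window 5, k = 5 negatives, min count 3 (kept low to retain rare
misspelling variants), t = 1e-5, 5 epochs.

One bigram-phrasing pass precedes subsampling: adjacent pairs with
discounted association score `(c_ab − δ)·N/(c_a·c_b) > θ` (δ = 5, θ = 10)
are merged into single `a_b` tokens, greedily and without overlap.  The
learned bigram set is stored with the embedding and re-applied to windows
at representation time so phrased tokens hit their learned vectors.

A patient's `Text_p` is the element-wise mean of their in-vocabulary token
vectors (sum/max/min are available; the aggregator can be selected on
validation AUROC).  Patients whose window has no in-vocabulary token keep
the zero vector rather than being dropped — exclusion would silently
change cohort composition between models and break the paired comparison.

## Tabular features

`Aux_p` is a fixed-order length-15 vector: z-scored age, a three-way
gender one-hot (female, male, other — the third category is a fixed
contract), and z-scored occurrence counts of the 11 tracked ICPC codes
(prefix match on the first three characters; duplicates count multiply, as
no deduplication rule is defined for repeat complaints).  Normalisation
statistics come from the training split only; zero-variance features map
to 0 with a logged warning.  Min-max scaling is available by config.

## Prediction models and optimisation

All three models are a single logistic unit.  Training minimises mean
binary cross-entropy with Adam (lr 1e-3, β = 0.9/0.999) over shuffled
mini-batches of 64, for at most 300 epochs, returning the weights of the
best validation epoch.

Two optimisation choices deserve explanation:

* **Column standardisation as a preconditioner.**  Inputs are z-scored on
  training statistics before optimisation and the affine transform is
  folded back into the returned weights, so the fitted model operates on
  raw features — an exact reparametrisation, verified against an IRLS
  logistic fit.  It matters because mean-aggregated embedding features
  have standard deviations around 0.01 (averaging ~100 correlated token
  vectors concentrates the means) while z-scored tabular features sit at
  unit scale; without preconditioning the combined model cannot grow the
  text-block weights far enough inside the epoch budget and silently
  degenerates to the tabular model.

* **Early-stopping patience 30.**  With a rare outcome the validation BCE
  is dominated by a handful of events and plateaus transiently; patience
  10 reproducibly truncated training while validation loss was still
  improving (best epoch ~270 of 300 when allowed to continue).  Patience
  must span the plateau noise, not the noise-free ideal.

No explicit L2 penalty is applied by default (early stopping on validation
loss is the regulariser); a ridge term is config-exposed for
high-dimensional inputs.  Embeddings are frozen during model training —
only the logistic layer learns — and a test asserts the embedding matrix
is bit-identical afterwards.

## Evaluation protocol

All interval estimates come from 1000 bootstrap resamples of the fixed
test set; the same index vector is applied to every model within a
replicate, so model comparisons are paired.  Reported per metric: the
replicate median and the 2.5th/97.5th percentiles.  Significance of a
model pair: 0 outside the percentile interval of paired AUROC differences
(p < 0.05).  Resamples containing a single class are redrawn to keep the
replicate count fixed.

* AUROC uses the Mann–Whitney rank formulation, ties counted ½.
* AUPRC uses the step-wise precision-at-recall rule (no interpolation,
  which is biased in PR space); it equals average precision and is
  cross-checked against brute-force enumeration and scikit-learn.
* Specificity is reported at the *largest* threshold τ with
  sensitivity ≥ 0.95 (maximising specificity under the constraint).  τ is
  recomputed inside every bootstrap replicate — this is what produces the
  wide specificity intervals characteristic of rare outcomes, and is
  verified against exhaustive threshold search.
* Brier score is the mean squared error of predicted probabilities; skill
  scores are reported against the constant-prevalence and constant-zero
  baselines.
* Calibration curves are LOWESS smooths (span 0.6 by default; the span is
  a display choice, config-exposed) of outcome against prediction, clipped
  to [0, 1], annotated with the empirical 99th percentile of predictions:
  above it estimates rest on a handful of patients and are expected to
  look uncalibrated for an outcome this rare.  For n above a few thousand
  the smoother interpolates within 0.1 % of the prediction range, keeping
  cost linear without visible change.

## Synthetic cohort generator

The generator is the package's test bed and defines the study conditions;
it emulates distributional structure, not language.

Calibrated to a reference population of 60,641 patients (0.89 %
prevalence; female 55.05 % of controls / 51.76 % of cases; age brackets
[30–60)/[60–70)/[70–80)/[80–) at 68.62/13.88/8.04/9.46 % for controls and
23.48/24.95/25.69/25.88 % for cases; ~59 consultations per control and ~76
per case over the record).  Note lengths are 1–15 words with mode 7 at
probability 0.12.  Tokens come from a Zipf(1.05) inventory of 2,000
pseudo-words; notes receive occasional capitalisation, punctuation and
adjacent-character-swap typos for the cleaner to strip.  Codes are drawn
from the 11 tracked ICPC codes (12 % of emission mass) plus ~70 background
codes; each consultation carries Poisson(0.7) codes.

The planted signal inside a case's window (two years ending five months
before the D75 date): 20 designated mid-frequency tokens are emitted with
their odds multiplied by `signal_strength` (default 10), a designated
adjacent signal pair appears at `background_bigram_rate ×
signal_strength`, and the tracked codes fire at `icpc_effect` (default 3)
times their base rate.  `signal_strength = icpc_effect = 1` therefore
makes case and control windows distributionally identical, which the
leakage tests rely on.  The D75 code is emitted exactly once, at the
anchor, which is always the record's last event; case consultation counts
are scaled by the observed record fraction so diagnosis-censoring does not
change in-window consultation density.  Effect sizes were chosen to place
the three models in the AUROC 0.75–0.90 band on a 20,000-patient cohort —
the band reported for this problem at full scale — so the ordering
(combined > tabular) is detectable with the ~30 test-split cases such a
cohort yields.

The generator does **not** emulate: real Dutch morphology or syntax,
temporal trends in consultation behaviour, code–text correlation within a
consultation, comorbidity structure, or inter-practice variation.  Passing
tests therefore demonstrate that the pipeline recovers a planted
frequency-based signal under realistic sparsity and noise — not that any
particular AUROC is attainable on real records.

Two scale-dependent defaults differ between the library and the synthetic
pipeline configuration: the subsampling threshold is t = 1e-3 in pipeline
runs (the 2,000-type vocabulary has token frequencies ~100× a natural
clinical corpus, so the threshold scales accordingly to preserve the
keep-probability profile), while the library default stays t = 1e-5; and
pipeline examples use d = 50 at 20,000 patients, which one CPU completes
in ~3 minutes, rather than d = 300.

## Leakage guards

Checked by tests: no consultation outside a patient's window reaches any
downstream stage; embedding vocabulary never contains validation/test-only
tokens; normalisation statistics derive from the training split alone;
embeddings are frozen during model training; and an end-to-end null cohort
(no planted signal, demographics equalised between classes) yields
AUROC ∈ [0.45, 0.55] for all three models.  The null check runs at
elevated prevalence (0.15) on 10,000 patients: at 0.89 % prevalence a 20 %
test split holds ~18 cases and the null-AUROC sampling sd (~0.07) exceeds
the band half-width, so the check would be uninformative about leakage.

## Known limitations

* The generator's demographic differences (age mixture, gender share,
  consultation volume) are themselves legitimate predictive signal; the
  `Tab` model uses them.  Interpreting model comparisons on synthetic data
  requires remembering that *all* channels are planted by construction.
* Mini-batched SGNS updates are not literally per-pair SGD; gradients are
  exact but a pair inside a batch does not see the updates of earlier
  pairs in the same batch.
* Calendar arithmetic ignores leap years and month lengths by design.
* Bootstrap resamples the test set only; variability from the train/
  validation/test partition itself is out of scope.
* No temporal features (dates, ordering of consultations) are used — the
  design isolates the added value of the words themselves.
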