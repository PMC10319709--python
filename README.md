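# notecast

Risk models for **early detection of colorectal cancer (CRC) in primary
care**, built from routinely collected GP consultation records: coded
symptoms (ICPC) plus short, noisy free-text notes.

The scientific question the package operationalises: *do free-text
consultation notes add predictive value on top of the structured features
used by established CRC risk models?*  It answers this by developing,
evaluating and statistically comparing three logistic prediction models:

| model  | input |
|--------|-------|
| `Tab`    | age (normalised), gender (3-way one-hot), normalised counts of 11 symptom ICPC codes (D12, D11, D18, D01, D25, D16, T08, T03, B80, B82, K94) |
| `Txt`    | a d-dimensional patient text embedding `Text_p` |
| `TabTxt` | the concatenation of both blocks |

`Text_p` is an **embed-and-aggregate** representation: Word2Vec skip-gram
with negative sampling (SGNS) is trained *offline* on the cleaned notes of
the training split (plus notes of patients below the age gate), with bigram
phrasing and frequency subsampling; a patient is the element-wise **mean**
of their in-vocabulary token vectors.  For a centre word w, context c and
negatives n_i drawn from the unigram^(3/4) distribution, each step descends

```
L = −log σ(W_w·C_c) − Σ_{i=1..k} log σ(−W_w·C_{n_i})
```

Patients are labelled by the **first consultation carrying an ICPC code
with prefix D75** (colon/rectum malignancy); controls anchor at their last
visit.  Each patient contributes the two years of record ending **five
months before the anchor** (half-open window; month = 30 d, year = 365 d),
the gap guarding against suspicion bias.  Inclusion requires age > 30 at
the anchor and at least one non-empty note or tracked code in the window.
Models are trained on a stratified 60/20/20 split (BCE loss, Adam,
mini-batches of 64, early stopping on validation loss, ≤ 300 epochs).

Evaluation follows a **paired percentile bootstrap** of the test set
(1000 resamples): AUROC, AUPRC (step-wise area), specificity at the most
stringent threshold keeping sensitivity ≥ 0.95 (recomputed inside every
replicate), Brier score and Brier skill versus the constant-prevalence and
constant-zero baselines, plus LOWESS calibration curves with a
99th-percentile tail marker.  Two models differ significantly (p < 0.05)
when 0 lies outside the 2.5th–97.5th percentile interval of their paired
per-replicate AUROC differences.

Because real consultation-level EMR data cannot be shipped, the package
includes a first-class **synthetic cohort generator** that emulates the
relevant structure: ~0.89 % CRC prevalence, note lengths 1–15 words with
mode 7, a Zipf(1.05) token inventory with typos and punctuation, and a
planted signal — inside a case's pre-diagnosis window, designated signal
tokens are emitted with boosted odds and the 11 symptom codes fire at an
elevated rate.  Every record encodes its outcome only the way a real EMR
does (a D75-coded consultation), so the labelling logic is exercised for
real.

## Worked example

```python
from notecast.pipeline import RunConfig, Seeds, run_all

config = RunConfig(n_patients=20_000, dim=50, seeds=Seeds.from_base(7))
report = run_all(config)
for kind, block in report["models"].items():
    m = block["metrics"]["auroc"]
    print(f"{kind:7s} AUROC {m['median']:.3f} ({m['ci_low']:.3f}-{m['ci_high']:.3f})")
print(report["comparisons"]["Tab-TabTxt"])
```

prints (2–3 minutes on one CPU):

```
Tab     AUROC 0.792 (0.693-0.879)
Txt     AUROC 0.821 (0.725-0.886)
TabTxt  AUROC 0.847 (0.751-0.920)
{'median_diff': -0.0547, 'ci_low': -0.106, 'ci_high': -0.0058, 'significant': True}
```

Reading: on a 20,000-patient synthetic cohort with planted text and code
signal, the combined model discriminates best; the paired interval of
`AUROC(Tab) − AUROC(TabTxt)` excludes 0, so adding free-text features to
the structured baseline is a statistically significant improvement — the
qualitative finding the pipeline is designed to detect.  `Txt` alone is
not significantly different from `Tab`, and with `signal_strength=1,
icpc_effect=1` (and equal demographics) all three models sit at
AUROC ≈ 0.5.

The same stages are scriptable from the shell (`notecast synth`, `cohort`,
`embed`, `train`, `predict`, `evaluate`, `run`); `notecast run --config
run.yaml` executes everything and writes windows, split, embeddings,
features, models, scores, plots and `report.json` to a run directory.

## Layout

```
src/notecast/
  records.py    consultation/patient record types + JSON Lines I/O
  synth.py      seeded synthetic EMR cohorts with a plantable signal
  cohort.py     cleaning, D75 labelling, windows, inclusion, stratified split
  embed.py      vocabulary, bigram phrasing, subsampling, SGNS (from scratch)
  represent.py  Text_p aggregation and Aux_p tabular features
  models.py     Tab/Txt/TabTxt logistic models (Adam + early stopping)
  evaluate.py   AUROC/AUPRC/specificity@sens/Brier/BSS, LOWESS calibration,
                paired percentile bootstrap
  pipeline.py   end-to-end orchestration under one seeded YAML config
  cli.py        `notecast` command group
docs/methods.md   model, assumptions, parameter choices, limitations
```
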