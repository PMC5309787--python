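# oncoresponse

Preclinical drug-response analysis for colorectal-cancer model cohorts:
patient-derived organoids (PDO) screened in dose-response plates and
patient-derived xenografts (PDX) followed by calliper measurement, with
matched bulk RNA-seq expression (RPKM). The package quantifies drug
sensitivity from raw assay measurements, derives drug-response gene
signatures, and builds a small class-weighted linear-SVM panel
("mini-classifier") that predicts treatment response — the kind of
pipeline used to nominate expression biomarkers for drugs such as
cetuximab (EGFR blockade) and 5-fluorouracil, and to compare them
against KRAS/NRAS/BRAF mutation status.

It is aimed at computational biologists working with preclinical
model cohorts who need the full chain — assay scoring, signature
derivation, classifier training, honest cross-validation — as tested,
reusable code. A synthetic-cohort generator with known ground truth
makes every stage testable without access-controlled patient data.

## What it computes

**Organoid potency.** Plate luminescence is normalized to percent
inhibition against vehicle and staurosporine controls, replicate means
are fit with the four-parameter logistic
`y(c) = bottom + (top − bottom) / (1 + (IC50/c)^hill)` on the log10
concentration scale, and the relative IC50 (curve inflection) plus
Emax (inhibition at the top tested concentration) are reported. IC50
maps to four response categories (strong / moderate / minor /
resistant at 0.0361 / 0.4277 / 5.0656 µM).

**Xenograft efficacy.** Tumour volume V = length × width²/2; endpoint
T/C = 100 × mean treated / mean control volume, categorized at
10 / 25 / 50%; relative tumour volume (end/start) mapped to
RECIST-adapted CR/PR/SD/PD at 0 / 0.7 / 1.2; responders are models
with T/C ≤ 25%. PDO/PDX sibling responses are concordant when their
categories differ by at most one rank.

**Signatures.** Per-drug differential expression in four setups over
the response categories (group contrasts and a continuous-phenotype
linear association), filtered at FDR ≤ 0.01, |log2 FC| ≥ 1, RPKM
difference ≥ 1 (dispersion < 4 for the continuous setup) and a
low-expression floor, combined by union with per-gene provenance.

**Mini-classifier.** On z-scored log2 expression: correlated-pair
pruning (r ≥ 0.8), per-class SVM cost tuning (C_resis, C_resp) by
stratified-bootstrap F1, SVM-RFE feature ranking by the resampled
weight vector |w|, and feature-size selection by the
F1-then-sensitivity rule. Evaluation: repeated stratified 10-fold
cross-validation with the *entire* pipeline refit inside each training
fold, external-cohort validation with per-cohort z-scoring and an
SD-handling policy, and a mutation-status comparator.

See `docs/methods.md` for the full model description, defaults and
limitations.

## Worked example

Run the bundled pipeline on a synthetic 14-responder / 34-resistant
cohort with ten planted differential genes (log2 fold change 2):

```python
from oncoresponse.synthetic import SyntheticConfig, generate_cohort
from oncoresponse.classifier import MiniClassifierTrainer
from oncoresponse.evaluation import repeated_cross_validation

config = SyntheticConfig(seed=3)          # 14 vs 34, 200 genes, 10 planted
matrix, response, mutations, truth = generate_cohort(config)

trainer = MiniClassifierTrainer()          # signature -> prune -> tune -> RFE -> select
model = trainer.fit(matrix, truth.labels, seed=5)
print(len(model.genes), sorted(model.genes))

report, _ = repeated_cross_validation(
    matrix, truth.labels, MiniClassifierTrainer.fast_cv(),
    folds=10, repeats=10, seed=11)
print(f"balanced accuracy {report.balanced_accuracy:.3f} "
      f"sensitivity {report.sensitivity:.3f} specificity {report.specificity:.3f}")
```

Output:

```
8 ['G00000', 'G00001', 'G00002', 'G00004', 'G00006', 'G00007', 'G00008', 'G00009']
balanced accuracy 0.991 sensitivity 0.986 specificity 0.997
```

The selected 8-gene panel consists entirely of planted differential
genes (`G00000`–`G00009` are the ground-truth responders' genes), and
the cross-validated balanced accuracy — with signature derivation,
pruning, tuning, ranking and size selection all refit inside every
training fold — is far above the ≈0.5 obtained when the same pipeline
runs on a cohort with no planted effect (the permutation control).

The same stages are scriptable from the shell:

```sh
oncoresponse run --seed 3 --out-dir results/run1
oncoresponse doseresponse fit --input plate.csv --out fits.csv
oncoresponse xeno score --input growth.csv --out pdx_response.csv
oncoresponse signature derive --expr expr.tsv --response pdx_response.csv \
    --system PDX --out sig.txt
oncoresponse evaluate cv --expr expr.tsv --response response.csv --seed 7
```

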