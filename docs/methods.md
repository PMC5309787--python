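# Methods

`oncoresponse` quantifies preclinical drug response in patient-derived
organoids (PDO) and xenografts (PDX), derives drug-response gene
signatures from bulk RNA-seq expression (RPKM), and builds a small
class-weighted linear-SVM panel ("mini-classifier") that predicts
treatment response. This note documents the models, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate,
and the numerical choices that matter.

## Organoid dose-response

Raw luminescence readings are normalized per plate to percent growth
inhibition against vehicle (maximum signal) and 5 µM staurosporine
(minimum signal) controls:

    inhibition = 100 * (max_ctrl - reading) / (max_ctrl - min_ctrl)

Values outside [0, 100] are retained (biological overshoot). Replicate
means are fit with the four-parameter logistic on the
log10-concentration scale:

    y(c) = bottom + (top - bottom) / (1 + (IC50 / c)^hill)

The reported IC50 is the *relative* IC50 — the curve inflection — not
the absolute 50% crossing. Emax is the mean observed inhibition at the
highest tested concentration, independent of the fit. Fitting uses
bounded trust-region least squares from a heuristic start (bottom =
min, top = max, IC50 = geometric mid-concentration, hill = 1) plus
five deterministically jittered restarts, keeping the best SSE. Curves
whose response spans less than 10 percentage points are declared
unconverged with the IC50 censored above the tested range; downstream
categorization treats them as resistant, so every screened model
receives a category. IC50 categories (µM): strong ≤ 0.0361 < moderate
≤ 0.4277 < minor ≤ 5.0656 < resistant, boundaries inclusive on the
sensitive side. For the antibody case, categories are defined on
log10(IC50) with bounds (−5.777, −3.63, −1.483); the published bounds
leave an interval between −5.777 and −4.703 unassigned, which this
implementation folds into the moderate class — those boundaries should
not be treated as authoritative. Concentrations are canonicalized to
µM; ng/ml inputs are converted with a supplied molecular weight.

Emax uses the replicate mean (the alternative, best replicate, is not
implemented); drug-drug sensitivity correlation uses Spearman rank
correlation on pairwise-complete model profiles with a three-model
minimum per pair.

## Xenograft endpoints

Tumour volume from calliper measurements: V = length × width² / 2
(mm³), with length/width swap-normalized on ingest. Endpoint T/C is
100 × mean(treated volumes) / mean(control volumes) at the last study
day present in both arms (nearest-day alignment with a ±2-day
tolerance; the arm summary is the arithmetic mean over animals —
median is a deliberate non-default). Categories: strong ≤ 10 <
moderate ≤ 25 < minor ≤ 50 < resistant; the responder binarization for
classifier training is T/C ≤ 25 (strong or moderate). Relative tumour
volume RTV = end/start volume maps to RECIST-adapted calls: CR at 0,
PR below 0.7, SD in [0.7, 1.2], PD above 1.2 — a partition of the
non-negative reals. Arm-level RTV is the mean of per-animal RTVs; a CR
call requires every treated animal to end at zero volume. PDO/PDX
sibling responses are concordant when their four-level categories
differ by at most one rank.

## Signature discovery

Differential expression runs in four setups over the four-category
response scale: (a) strong+moderate vs minor+resistant, (b)
strong+moderate+minor vs resistant, (c) the 20 (PDX) or 10 (PDO) most
vs least sensitive models, and (d) a per-gene linear association of
log2 expression with the continuous phenotype (T/C or IC50). The
two-group statistic defaults to Welch's t on log2(RPKM + 1) and is
pluggable; a count-model backend can be substituted when counts are
available, while the filters are fixed here: setups a–c require
BH FDR ≤ 0.01, |log2 FC| ≥ 1 (computed on RPKM group means with a 0.1
pseudocount) and an absolute RPKM mean difference ≥ 1; setup d
requires FDR ≤ 0.01 and excludes genes with RPKM dispersion
(variance/mean) ≥ 4 — dispersion is deliberately defined on the RPKM
scale since a negative-binomial dispersion is not estimable from RPKM
alone. The signature is the union over setups, intersected with an
expression floor (≥ 1 RPKM in at least five PDX or three PDO samples
and mean ≥ 0.8 RPKM), with per-gene setup provenance recorded and a
deterministic gene order (descending best |log2 FC|, ties by gene id),
so assembly is invariant to setup order.

Variable-gene selection uses the quantile absolute deviation
QAD = P75(|x − median(x)|) (linear-interpolation quantile), requiring
a gene to rank in the top fraction under both the raw and the
log2-transformed values. Mean-pattern matrices z-score each gene's
log2 expression across samples (or against stored reference means/sds
when projecting onto a patient cohort) and summarize each signature by
a trimmed mean over its genes; the trim proportion (scipy's per-tail
`proportiontocut`) defaults to 0.25, a free parameter. The PDX/PDO
pair-ranking score combines fold change f (0.1 pseudocount) and log2
difference d as r = sign(f)·sqrt(|f|·|d|), zero when the signs
disagree (for plain paired RPKM values disagreement only occurs at
exact equality; a `signed` mode keeps sign(f) regardless). The
descending r vector is a complete ranking suitable as pre-ranked
enrichment input; the enrichment engine itself is out of scope.

## The mini-classifier

Features are z-scored log2(RPKM + 1) values with the per-gene
mean/sd stored for reuse. Before training, highly correlated gene
pairs (Pearson r ≥ 0.8) are pruned over two iterations, dropping the
member with the lower (pre-scaling) mean expression; pairs are visited
in descending correlation order with lexicographic tie-breaks, making
pruning deterministic.

The classifier is a soft-margin linear SVM minimizing
½‖w‖² + Σᵢ C_class(i)·ξᵢ with separate misclassification costs for the
resistant and responder classes (C_resis, C_resp) to address the
~14-vs-34 class imbalance. It is fit with libsvm (scikit-learn `SVC`,
linear kernel, per-class weights), the same backend family as the R
package the protocol this mirrors was built on. Cost pairs are tuned
by grid search under a stratified bootstrap (resamples shared across
grid points; out-of-bag F1 on the responder class; ties prefer smaller
costs). The default grid covers 0.001–5 per class and includes the
reference optima 0.05/0.3; the 5-FU-style preset adds 0.007.

Feature ranking is an adapted SVM-RFE: each recursive step re-tunes
the costs, fits the SVM on stratified leave-n-out resamples (default
leave-out fraction 0.2 — the protocol's n is not fixed anywhere, so
this is a declared default), scores each feature by the mean |w| over
resamples (the weight vector itself, not w²; the absolute value stops
sign flips across resamples from cancelling), and eliminates the
lowest-scoring features — the bottom 10% while more than 50 remain,
then one at a time. Feature-size selection evaluates (cost pair,
top-k panel) candidates by bootstrap F1 and sensitivity; candidates
are ranked by F1 and, among the top m (default 3; the 5-FU preset uses
11), the one with the highest sensitivity wins, ties going to higher
F1 and then the smaller panel. Candidate panel sizes default to
8-20 genes, bracketing the scale of the published panels; on clean
synthetic cohorts where bootstrap F1 saturates, the smallest candidate
size wins by the tie-break, so the lower end of this range sets the
floor on panel size. The winner is refit on all training
data. Decision values of exactly zero predict resistant — the
conservative call for treatment selection. Cost tuning happens once
per RFE step (not per resample), matching the stated order of the
procedure.

The mutation-status comparator predicts resistance from qualifying
calls: KRAS codons 12/13 only (`kras_codon12_13`, for cohorts with
limited genotyping), or KRAS/NRAS at codons 12, 13, 22, 61, 146 plus
BRAF V600E (`all_ras_raf`). Unparseable protein changes warn and count
as wild type.

## Evaluation

Performance reports carry TP/FP/TN/FN and sensitivity, specificity,
balanced accuracy ((sens+spec)/2) and F1 (positive class = responder);
metrics undefined for the observed counts are `None`, never silently
zero. Cross-validation is repeated stratified k-fold (default 10-fold)
in which *every* trained step — differential expression, pruning,
scaling, cost tuning, RFE, size selection — refits inside each
training fold; per-repeat metrics (confusion counts pooled over folds)
are averaged across repeats. External cohorts are log2-transformed if
needed and z-scored *within the cohort*, replacing the training scaler
— this removes cohort-wide location/scale shifts (a global +2 log2
batch offset leaves predictions unchanged, which the tests verify).
CR/PR map to responder truth and PD to non-responder; SD samples
follow a policy (counted as non-responders by default, or excluded
with the exclusion count reported). Evaluation can be restricted to
KRAS-wild-type or all-RAS/RAF-wild-type strata via the mutation rules.
At least 80% of panel genes must map to the cohort's identifiers.
Classifier-vs-mutation comparison is descriptive (side-by-side metrics
with deltas), with no significance testing.

## Synthetic cohorts

The generator supplies fully specified cohorts so every stage is
testable without controlled-access data. Expression: log2(RPKM + 1) of
each gene is Normal(µ_g, sd) with µ_g uniform on a configured log2
range (default 2–8) and sd defaulting to 1; planted differential genes
shift the responder-group mean by a configured log2 fold change
(default 2, ten genes); correlated pairs share a latent signal with
partner noise solved from the target correlation (default 0.9), the
partner taking the lower baseline mean so pruning direction is known;
a configured fraction of genes (default 0.1) is forced below 1 RPKM
mean to exercise the low-expression filters. The default cohort is 14
responders vs 34 resistant over 200 genes, the class structure of the
training cohorts this pipeline targets. Response labels come from
thresholding a standardized score over the planted genes (signature
link), from planted qualifying mutations (mutation link), or both
(mixed), with matched T/C values (responders uniform on (2, 25],
resistant on (25, 120]). Dose-response curves place replicates on a
4PL curve with additive Gaussian noise; growth series follow
exponential growth with multiplicative log-normal noise and a
fractional treatment effect on the growth rate, emitted as calliper
pairs under a fixed length = 1.2 × width convention so volumes
round-trip exactly.

What the generator does *not* emulate: count-level sampling noise
(expression is Gaussian on the log scale, not negative binomial),
mouse-stroma contamination, batch structure beyond a global shift,
within-class response heterogeneity, or linkage between expression
signatures and mutations beyond the configured label links. Passing
tests therefore demonstrate that the algorithms are implemented
correctly and recover planted structure at realistic sizes and noise
levels — not that the specific published gene panels would be
re-derived from real cohorts, which require controlled-access data.

## Problem sizes and budgets

Resampling defaults in `MiniClassifierTrainer` are simulation scale:
25 bootstrap iterations for cost tuning, 50 leave-n-out resamples for
ranking, a 5×5 cost grid. A production run on a real cohort should
raise these to the protocol scale (100/200, full grid) via the
`cetuximab`/`5fu` presets. Inside repeated cross-validation — where
the full pipeline refits in every fold — the package uses a further
reduced budget (3×3 grid, 10/20 resamples, `fast_cv`): balanced
accuracy estimates are driven by the final panel fit and are robust to
the inner tuning budget, while the refit-everything protocol is what
guards against selection leakage. The acceptance script runs 10
repeats of 10-fold CV; the published protocol's 100 repeats change
only the averaging precision.

## Known limitations

* The count-based differential-expression backend of the original
  protocol is approximated by Welch's t on log2 RPKM; planted-effect
  recovery is calibrated for this test, and the hook accepts any
  per-gene two-group statistic.
* Gene-identifier mapping to external platforms is a user-supplied
  dictionary; no online lookup.
* The four-category IC50 boundaries are assay-specific constants;
  applying them to differently normalized potency values is the
  caller's responsibility.
* `categorize_pdo`'s log-unit scale inherits the unresolved gap in the
  published antibody boundaries (see above).
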