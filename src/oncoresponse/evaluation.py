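"""Predictor performance measurement.

Confusion-count metrics (sensitivity, specificity, balanced accuracy,
F1) for responder prediction, repeated stratified k-fold
cross-validation with every trained step refit inside each training
fold, the external-cohort validation protocol (per-cohort z-scoring,
CR/PR/SD/PD truth mapping with a stable-disease policy, mutation-based
sample strata), and side-by-side classifier-vs-mutation-status
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .classifier import SvmModel, mutation_status_predictor, predict
from .matrix import ExpressionMatrix

__all__ = [
    "PerformanceReport",
    "ExternalCohort",
    "confusion_and_metrics",
    "repeated_cross_validation",
    "external_validation",
    "compare_predictors",
]


class EvaluationError(ValueError):
    pass


@dataclass
class PerformanceReport:
    """Confusion counts plus derived metrics for a responder predictor.

    Metrics that are undefined for the given counts (e.g. sensitivity
    with no true responders) are ``None``, never silently zero.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    balanced_accuracy: float | None
    f1: float | None
    n_excluded: int = 0
    stratum: str = "all"

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_and_metrics(y_true, y_pred, stratum: str = "all",
                          n_excluded: int = 0) -> PerformanceReport:
    """Confusion counts and metrics; positive class = responder."""
    yt = np.asarray(y_true, dtype=bool)
    yp = np.asarray(y_pred, dtype=bool)
    if yt.shape != yp.shape:
        raise EvaluationError(f"length mismatch: {yt.shape} vs {yp.shape}")
    if yt.size == 0:
        raise EvaluationError("need >=1 sample")
    tp = int(np.sum(yp & yt))
    fp = int(np.sum(yp & ~yt))
    tn = int(np.sum(~yp & ~yt))
    fn = int(np.sum(~yp & yt))
    sens = tp / (tp + fn) if tp + fn else None
    spec = tn / (tn + fp) if tn + fp else None
    bal = (sens + spec) / 2 if sens is not None and spec is not None else None
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else None
    return PerformanceReport(tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sens,
                             specificity=spec, balanced_accuracy=bal, f1=f1,
                             n_excluded=n_excluded, stratum=stratum)


def repeated_cross_validation(
    matrix: ExpressionMatrix,
    y: pd.Series,
    trainer,
    folds: int = 10,
    repeats: int = 100,
    seed: int = 0,
    predict_mode: str = "stored",
) -> tuple[PerformanceReport, pd.DataFrame]:
    """Repeated stratified k-fold CV of a full training pipeline.

    ``trainer.fit(train_matrix, y_train, seed)`` must return a model
    with a compatible ``predict``; every trained step runs inside the
    training fold only.  Per-repeat confusion counts are pooled over
    folds into per-repeat metrics, which are then averaged across
    repeats.  Returns the averaged report and the per-repeat table.
    """
    ya = y.loc[matrix.sample_ids].astype(bool)
    n_min = int(min(ya.sum(), (~ya).sum()))
    if n_min < 2:
        raise EvaluationError("each class needs >=2 members")
    if n_min < folds:
        warnings.warn(f"reducing folds from {folds} to {n_min} "
                      "(minority class too small)")
        folds = n_min
    rng = np.random.default_rng(seed)
    samples = np.array(matrix.sample_ids)
    yarr = ya.to_numpy()

    per_repeat = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        yt_all, yp_all = [], []
        for train_idx, test_idx in skf.split(samples, yarr):
            train_m = matrix.subset_samples(list(samples[train_idx]))
            test_m = matrix.subset_samples(list(samples[test_idx]))
            model = trainer.fit(train_m, ya.iloc[train_idx],
                                seed=int(rng.integers(2 ** 31)))
            pred = predict(model, test_m, mode=predict_mode)
            yt_all.append(yarr[test_idx])
            yp_all.append(pred["predicted_responder"].to_numpy())
        rep_report = confusion_and_metrics(np.concatenate(yt_all),
                                           np.concatenate(yp_all))
        per_repeat.append({
            "repeat": rep,
            "sensitivity": rep_report.sensitivity,
            "specificity": rep_report.specificity,
            "balanced_accuracy": rep_report.balanced_accuracy,
            "f1": rep_report.f1,
            "tp": rep_report.tp, "fp": rep_report.fp,
            "tn": rep_report.tn, "fn": rep_report.fn,
        })
    table = pd.DataFrame(per_repeat)
    mean = table[["sensitivity", "specificity", "balanced_accuracy", "f1"]].mean()
    avg = PerformanceReport(
        tp=int(round(table["tp"].mean())), fp=int(round(table["fp"].mean())),
        tn=int(round(table["tn"].mean())), fn=int(round(table["fn"].mean())),
        sensitivity=float(mean["sensitivity"]),
        specificity=float(mean["specificity"]),
        balanced_accuracy=float(mean["balanced_accuracy"]),
        f1=float(mean["f1"]), stratum="cv",
    )
    return avg, table


@dataclass
class ExternalCohort:
    """An independent validation cohort.

    ``response`` holds CR/PR/SD/PD calls (or the four-category scale
    already binarized upstream); ``log2_transformed`` says whether the
    expression values are already on the log2 scale.  ``gene_map``
    optionally maps model gene ids to this cohort's identifiers.
    """

    cohort_id: str
    expression: ExpressionMatrix
    response: pd.Series
    mutations: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["sample_id", "gene", "protein_change"]))
    log2_transformed: bool = False
    gene_map: dict[str, str] | None = None


def external_validation(
    model: SvmModel,
    cohort: ExternalCohort,
    sd_policy: str = "include_as_nonresponder",
    stratum: str = "all",
    min_mapped: float = 0.8,
) -> PerformanceReport:
    """Validate the panel on an external cohort, per-cohort z-scored.

    The cohort expression is log2-transformed if needed and z-scored
    within the cohort (replacing the training scaler, which removes
    cohort-wide location/scale shifts).  Truth mapping: CR/PR ->
    responder, PD -> non-responder, SD per ``sd_policy``
    ('include_as_nonresponder' or 'exclude').  ``stratum`` restricts
    evaluation to mutation-defined subsets ('all', 'kras_wt',
    'all_ras_raf_wt').  At least ``min_mapped`` of the panel genes must
    be mappable.
    """
    if sd_policy not in ("include_as_nonresponder", "exclude"):
        raise EvaluationError(f"unknown sd_policy {sd_policy!r}")
    if stratum not in ("all", "kras_wt", "all_ras_raf_wt"):
        raise EvaluationError(f"unknown stratum {stratum!r}")

    expr = cohort.expression
    genes = list(model.genes)
    if cohort.gene_map is not None:
        mapped = {g: cohort.gene_map[g] for g in genes if g in cohort.gene_map}
    else:
        mapped = {g: g for g in genes if g in expr.values.index}
    if len(mapped) < min_mapped * len(genes):
        missing = sorted(set(genes) - set(mapped))
        raise EvaluationError(
            f"only {len(mapped)}/{len(genes)} panel genes map to cohort "
            f"{cohort.cohort_id}; unmapped: {missing}")

    values = expr.values
    if cohort.log2_transformed:
        rpkm_like = np.exp2(values) - 1.0  # back to linear for the shared path
        values = rpkm_like.clip(lower=0.0)
    sub = ExpressionMatrix(
        values.loc[list(mapped.values())].set_axis(list(mapped.keys()), axis=0))
    eval_model = SvmModel(
        genes=[g for g in genes if g in mapped],
        w=np.array([model.w[genes.index(g)] for g in genes if g in mapped]),
        b=model.b, c_resis=model.c_resis, c_resp=model.c_resp,
    )

    resp = cohort.response
    samples = [s for s in sub.sample_ids if s in resp.index]
    truth_map = {"CR": True, "PR": True, "PD": False}
    keep, truth = [], []
    n_excluded = 0
    for s in samples:
        call = str(resp[s]).upper()
        if call == "SD":
            if sd_policy == "exclude":
                n_excluded += 1
                continue
            keep.append(s); truth.append(False)
        elif call in truth_map:
            keep.append(s); truth.append(truth_map[call])
        elif call in ("TRUE", "FALSE"):  # pre-binarized
            keep.append(s); truth.append(call == "TRUE")
        else:
            raise EvaluationError(f"unknown response call {resp[s]!r} for {s}")

    if stratum != "all":
        mode = "kras_codon12_13" if stratum == "kras_wt" else "all_ras_raf"
        wt = mutation_status_predictor(cohort.mutations, keep, mode=mode)
        filtered = [s for s in keep if wt[s]]
        n_excluded += len(keep) - len(filtered)
        truth = [t for s, t in zip(keep, truth) if wt[s]]
        keep = filtered

    if not keep:
        warnings.warn("no sample left to evaluate after exclusions")
        return PerformanceReport(0, 0, 0, 0, None, None, None, None,
                                 n_excluded=n_excluded, stratum=stratum)

    pred = predict(eval_model, sub.subset_samples(keep), mode="per_cohort")
    report = confusion_and_metrics(
        np.array(truth), pred["predicted_responder"].to_numpy(),
        stratum=stratum, n_excluded=n_excluded)
    return report


def compare_predictors(classifier_report: PerformanceReport,
                       mutation_report: PerformanceReport) -> pd.DataFrame:
    """Side-by-side metrics with deltas (classifier - mutation status).

    Descriptive only — no significance testing.  Both reports must
    cover the same evaluated sample set.
    """
    if classifier_report.n != mutation_report.n:
        raise EvaluationError(
            f"reports cover different sample counts: "
            f"{classifier_report.n} vs {mutation_report.n}")
    rows = []
    for metric in ("sensitivity", "specificity", "balanced_accuracy", "f1"):
        a = getattr(classifier_report, metric)
        b = getattr(mutation_report, metric)
        delta = a - b if a is not None and b is not None else None
        rows.append({"metric": metric, "classifier": a,
                     "mutation_status": b, "delta": delta})
    return pd.DataFrame(rows).set_index("metric")
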