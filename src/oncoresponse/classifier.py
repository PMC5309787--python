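"""Drug-response mini-classifier.

A class-weighted linear SVM over a small gene panel, built from a
drug-response signature by:

1. z-scoring log2 expression (scaler stored for reuse),
2. pruning highly correlated gene pairs (Pearson r >= 0.8, dropping the
   lower-mean member, two iterations),
3. per-class cost tuning (C_resis, C_resp) by grid search with a
   stratified bootstrap scored by F1 on the responder class,
4. recursive feature elimination (SVM-RFE) where each step re-tunes the
   costs and scores features by the mean |w| of the SVM weight vector
   over stratified leave-n-out resamples (w, not w^2),
5. feature-size selection: among the top-m candidate configurations by
   F1, the one with the highest sensitivity wins.

The imbalance handling follows the training cohorts this mirrors
(around 14 responding vs 34 resistant models): separate misclassification
costs per class, with F1 on the scarce responder class as the tuning
objective.  A mutation-status comparator (KRAS codon 12/13, or
all-RAS/RAF) provides the clinical baseline predictor.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .matrix import ExpressionMatrix
from .signatures import differential_expression, expression_filter

__all__ = [
    "FeatureScaler",
    "SvmModel",
    "RankingResult",
    "SelectionCandidate",
    "preprocess_features",
    "prune_correlated",
    "train_weighted_linear_svm",
    "tune_costs",
    "svm_rfe_rank",
    "apply_selection_rule",
    "select_model",
    "predict",
    "mutation_status_predictor",
    "MiniClassifierTrainer",
    "COST_GRID_DEFAULT",
    "COST_GRID_SMALL",
    "COST_GRID_TINY",
]

# Per-class cost grid covering the published optima (0.05/0.3 cetuximab,
# 0.007/0.02 5-FU; 0.007 is included for the 5-FU preset).
COST_VALUES_DEFAULT = (0.001, 0.002, 0.005, 0.01, 0.02, 0.05,
                       0.1, 0.2, 0.3, 0.5, 1.0, 2.0, 5.0)
COST_VALUES_5FU = (0.001, 0.002, 0.005, 0.007, 0.01, 0.02, 0.05,
                   0.1, 0.2, 0.3, 0.5, 1.0, 2.0, 5.0)
COST_GRID_DEFAULT = tuple((cr, cp) for cr in COST_VALUES_DEFAULT
                          for cp in COST_VALUES_DEFAULT)
# Reduced grid for simulation-scale runs.
COST_VALUES_SMALL = (0.01, 0.05, 0.1, 0.3, 1.0)
COST_GRID_SMALL = tuple((cr, cp) for cr in COST_VALUES_SMALL
                        for cp in COST_VALUES_SMALL)
# Minimal grid for the inner loop of repeated cross-validation, where
# the whole pipeline refits in every training fold.
COST_VALUES_TINY = (0.01, 0.1, 1.0)
COST_GRID_TINY = tuple((cr, cp) for cr in COST_VALUES_TINY
                       for cp in COST_VALUES_TINY)


class TrainingError(ValueError):
    pass


class PredictionError(ValueError):
    pass


@dataclass
class FeatureScaler:
    """Per-gene mean/sd on the log2(RPKM + 1) scale, fit on training data."""

    mean: pd.Series
    sd: pd.Series
    dropped: list[str] = field(default_factory=list)

    def transform_log2(self, log2: pd.DataFrame) -> pd.DataFrame:
        """Apply to a genes x samples log2 table; returns samples x genes."""
        sub = log2.loc[self.mean.index]
        return sub.sub(self.mean, axis=0).div(self.sd, axis=0).T


def preprocess_features(
    matrix: ExpressionMatrix, genes: list[str]
) -> tuple[pd.DataFrame, FeatureScaler]:
    """z-score log2(RPKM + 1) per gene; returns samples x genes table.

    Zero-variance genes cannot be scaled and are dropped with a warning
    (recorded on the scaler).
    """
    if matrix.n_samples < 2:
        raise TrainingError("need >=2 samples to fit a scaler")
    log2 = matrix.log2().loc[list(genes)]
    mean = log2.mean(axis=1)
    sd = log2.std(axis=1, ddof=1)
    dropped = list(sd.index[sd == 0])
    if dropped:
        warnings.warn(f"dropping zero-variance genes: {dropped}")
        log2 = log2.drop(index=dropped)
        mean = mean.drop(index=dropped)
        sd = sd.drop(index=dropped)
    scaler = FeatureScaler(mean=mean, sd=sd, dropped=dropped)
    return scaler.transform_log2(log2), scaler


def prune_correlated(
    log2_features: pd.DataFrame, threshold: float = 0.8, iterations: int = 2
) -> list[str]:
    """Drop the lower-mean member of highly correlated gene pairs.

    ``log2_features`` is a samples x genes table of unscaled log2
    expression (means are taken pre-scaling).  Per iteration, pairs
    with Pearson r >= ``threshold`` are visited in descending
    correlation order; when both members are still present, the one
    with the lower mean is dropped (ties by lexicographic gene id).
    """
    kept = list(log2_features.columns)
    means = log2_features.mean(axis=0)
    for _ in range(iterations):
        if len(kept) < 2:
            break
        corr = log2_features[kept].corr()
        pairs = []
        for i, g1 in enumerate(kept):
            for g2 in kept[i + 1:]:
                r = corr.loc[g1, g2]
                if np.isfinite(r) and r >= threshold:
                    pairs.append((r, g1, g2))
        pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
        alive = set(kept)
        for _, g1, g2 in pairs:
            if g1 in alive and g2 in alive:
                if means[g1] < means[g2] or (means[g1] == means[g2] and g1 > g2):
                    alive.discard(g1)
                else:
                    alive.discard(g2)
        kept = [g for g in kept if g in alive]
    return kept


@dataclass
class SvmModel:
    """Linear SVM panel: prediction = sign(w . x + b), positive = responder."""

    genes: list[str]
    w: np.ndarray
    b: float
    c_resis: float
    c_resp: float
    scaler: FeatureScaler | None = None
    positive_class: str = "responder"

    def decision_values(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.w + self.b

    def predict_features(self, X) -> np.ndarray:
        """Boolean responder calls; ties (decision exactly 0) -> resistant."""
        return self.decision_values(X) > 0


def train_weighted_linear_svm(
    X, y, c_resis: float, c_resp: float, genes: list[str] | None = None
) -> SvmModel:
    """Soft-margin linear SVM minimizing 0.5 ||w||^2 + sum_i C_class(i) xi_i.

    Per-class costs address class imbalance; the problem is convex so
    the result is deterministic for fixed input.
    """
    if c_resis <= 0 or c_resp <= 0:
        raise TrainingError("costs must be positive")
    if isinstance(X, pd.DataFrame):
        genes = genes if genes is not None else list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        genes = genes if genes is not None else [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=bool)
    if y.all() or not y.any():
        raise TrainingError("training labels contain a single class")
    clf = SVC(kernel="linear", C=1.0, class_weight={0: c_resis, 1: c_resp},
              tol=1e-6)
    clf.fit(X, y.astype(int))
    return SvmModel(genes=list(genes), w=clf.coef_.ravel().copy(),
                    b=float(clf.intercept_[0]), c_resis=c_resis, c_resp=c_resp)


def _f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum(y_pred & y_true))
    fp = int(np.sum(y_pred & ~y_true))
    fn = int(np.sum(~y_pred & y_true))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def _stratified_bootstrap(y: np.ndarray, rng: np.random.Generator,
                          max_retries: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """In-bag (per-class with replacement) and out-of-bag index sets.

    Redrawn (bounded retries) until the out-of-bag set contains both
    classes, so F1 is always computable.
    """
    idx = np.arange(y.size)
    for _ in range(max_retries):
        bag = np.concatenate([
            rng.choice(idx[y], size=int(y.sum()), replace=True),
            rng.choice(idx[~y], size=int((~y).sum()), replace=True),
        ])
        oob = np.setdiff1d(idx, bag)
        if oob.size and y[oob].any() and (~y[oob]).any():
            return bag, oob
    raise TrainingError("could not draw an out-of-bag set with both classes")


def _fit_raw(X: np.ndarray, y: np.ndarray, c_resis: float, c_resp: float):
    clf = SVC(kernel="linear", C=1.0, class_weight={0: c_resis, 1: c_resp})
    clf.fit(X, y.astype(int))
    return clf.coef_.ravel(), float(clf.intercept_[0])


@dataclass
class TuneResult:
    c_resis: float
    c_resp: float
    f1: float
    table: pd.DataFrame = field(repr=False, default=None)


def tune_costs(
    X, y, grid=COST_GRID_DEFAULT, n_boot: int = 100, seed: int = 0,
    _resamples=None,
) -> TuneResult:
    """Grid-search (C_resis, C_resp) by stratified-bootstrap mean F1.

    Each grid point is scored on the same ``n_boot`` resamples: train on
    the in-bag samples, compute F1 for the responder class out-of-bag,
    average.  Ties go to the smaller cost sum, then lexicographically.
    """
    if not grid:
        raise TrainingError("empty cost grid")
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    ya = np.asarray(y, dtype=bool)
    rng = np.random.default_rng(seed)
    resamples = _resamples or [_stratified_bootstrap(ya, rng) for _ in range(n_boot)]
    rows = []
    for c_resis, c_resp in grid:
        scores = []
        for bag, oob in resamples:
            w, b = _fit_raw(Xa[bag], ya[bag], c_resis, c_resp)
            pred = Xa[oob] @ w + b > 0
            scores.append(_f1(ya[oob], pred))
        rows.append((c_resis, c_resp, float(np.mean(scores))))
    table = pd.DataFrame(rows, columns=["c_resis", "c_resp", "f1"])
    best = min(rows, key=lambda r: (-r[2], r[0] + r[1], (r[0], r[1])))
    return TuneResult(c_resis=best[0], c_resp=best[1], f1=best[2], table=table)


def _stratified_subset(y: np.ndarray, leave_out_fraction: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Indices of a stratified leave-n-out training subset."""
    idx = np.arange(y.size)
    keep = []
    for cls in (True, False):
        members = idx[y == cls]
        k = max(1, int(round((1.0 - leave_out_fraction) * members.size)))
        keep.append(rng.choice(members, size=k, replace=False))
    return np.sort(np.concatenate(keep))


@dataclass
class RankingResult:
    """SVM-RFE feature ranking: best (last-eliminated) gene first."""

    genes: list[str]
    scores: dict[str, float]


def svm_rfe_rank(
    X, y, grid=COST_GRID_DEFAULT, n_boot: int = 100, n_resample: int = 200,
    leave_out_fraction: float = 0.2, seed: int = 0,
) -> RankingResult:
    """Recursive feature elimination with resampled weight-vector ranking.

    Each recursive step (1) re-tunes the per-class costs by bootstrap
    grid search, (2) fits the class-weighted SVM on stratified
    leave-n-out resamples, (3) scores every remaining feature by the
    mean |w| across resamples, and (4) eliminates the lowest-scoring
    features (the bottom 10% while more than 50 remain, else one at a
    time).  The elimination order, reversed, is the ranking.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"f{i}" for i in range(Xa.shape[1])]
    ya = np.asarray(y, dtype=bool)
    if ya.all() or not ya.any():
        raise TrainingError("labels contain a single class")
    rng = np.random.default_rng(seed)

    remaining = list(range(len(names)))
    eliminated: list[tuple[int, float]] = []
    while len(remaining) > 1:
        cols = np.array(remaining)
        tuned = tune_costs(Xa[:, cols], ya, grid=grid, n_boot=n_boot,
                           seed=int(rng.integers(2 ** 31)))
        weights = np.zeros(len(cols))
        drawn = 0
        attempts = 0
        while drawn < n_resample and attempts < 20 * n_resample:
            attempts += 1
            sub = _stratified_subset(ya, leave_out_fraction, rng)
            if ya[sub].all() or not ya[sub].any():
                continue
            w, _ = _fit_raw(Xa[np.ix_(sub, cols)], ya[sub],
                            tuned.c_resis, tuned.c_resp)
            weights += np.abs(w)
            drawn += 1
        weights /= max(drawn, 1)
        n_drop = max(1, int(0.1 * len(cols))) if len(cols) > 50 else 1
        order = np.argsort(weights, kind="stable")  # ascending score
        for j in order[:n_drop]:
            eliminated.append((remaining[j], float(weights[j])))
        drop = {remaining[j] for j in order[:n_drop]}
        remaining = [i for i in remaining if i not in drop]
    for i in remaining:
        eliminated.append((i, float("inf")))

    ranked = [names[i] for i, _ in reversed(eliminated)]
    scores = {names[i]: (s if np.isfinite(s) else 1.0) for i, s in eliminated}
    return RankingResult(genes=ranked, scores=scores)


@dataclass
class SelectionCandidate:
    """One (cost pair, feature size) configuration with resampled metrics."""

    c_resis: float
    c_resp: float
    k: int
    f1: float
    sensitivity: float
    specificity: float


def apply_selection_rule(candidates: list[SelectionCandidate],
                         top_m: int = 3) -> SelectionCandidate:
    """F1-then-sensitivity rule: among the top-m candidates by F1, pick
    the one with the highest sensitivity (ties: higher F1, smaller panel)."""
    if not candidates:
        raise TrainingError("no selection candidate")
    by_f1 = sorted(candidates,
                   key=lambda c: (-c.f1, c.k, c.c_resis + c.c_resp,
                                  (c.c_resis, c.c_resp)))
    shortlist = by_f1[:top_m]
    return sorted(shortlist, key=lambda c: (-c.sensitivity, -c.f1, c.k,
                                            (c.c_resis, c.c_resp)))[0]


def select_model(
    ranking: RankingResult, X, y, grid=COST_GRID_DEFAULT,
    candidate_sizes=(8, 12, 16, 20), top_m: int = 3,
    n_boot: int = 100, seed: int = 0, scaler: FeatureScaler | None = None,
) -> tuple[SelectionCandidate, SvmModel]:
    """Feature-size and cost selection by the F1-then-sensitivity rule.

    Every (cost pair, top-k panel) candidate is scored by stratified
    bootstrap (out-of-bag F1 and sensitivity).  Candidates are ranked
    by F1; among the ``top_m`` best, the one with the highest
    sensitivity wins (ties: higher F1, then smaller panel).  The
    winning configuration is refit on the full training data.
    """
    sizes = [k for k in candidate_sizes if 1 <= k <= len(ranking.genes)]
    if not sizes:
        raise TrainingError("no valid candidate feature size")
    if isinstance(X, pd.DataFrame):
        Xdf = X
    else:
        Xdf = pd.DataFrame(np.asarray(X, float),
                           columns=[f"f{i}" for i in range(np.asarray(X).shape[1])])
    ya = np.asarray(y, dtype=bool)
    rng = np.random.default_rng(seed)
    resamples = [_stratified_bootstrap(ya, rng) for _ in range(n_boot)]

    candidates: list[SelectionCandidate] = []
    for k in sizes:
        panel = ranking.genes[:k]
        Xk = Xdf[panel].to_numpy(dtype=float)
        for c_resis, c_resp in grid:
            f1s, sens, spec = [], [], []
            for bag, oob in resamples:
                w, b = _fit_raw(Xk[bag], ya[bag], c_resis, c_resp)
                pred = Xk[oob] @ w + b > 0
                truth = ya[oob]
                f1s.append(_f1(truth, pred))
                sens.append(np.sum(pred & truth) / max(truth.sum(), 1))
                spec.append(np.sum(~pred & ~truth) / max((~truth).sum(), 1))
            candidates.append(SelectionCandidate(
                c_resis=c_resis, c_resp=c_resp, k=k,
                f1=float(np.mean(f1s)), sensitivity=float(np.mean(sens)),
                specificity=float(np.mean(spec)),
            ))

    winner = apply_selection_rule(candidates, top_m)
    panel = ranking.genes[: winner.k]
    model = train_weighted_linear_svm(Xdf[panel], ya, winner.c_resis,
                                      winner.c_resp, genes=panel)
    model.scaler = _subset_scaler(scaler, panel) if scaler is not None else None
    return winner, model


def _subset_scaler(scaler: FeatureScaler, genes: list[str]) -> FeatureScaler:
    return FeatureScaler(mean=scaler.mean.loc[genes].copy(),
                         sd=scaler.sd.loc[genes].copy(),
                         dropped=list(scaler.dropped))


def predict(model: SvmModel, matrix: ExpressionMatrix,
            mode: str = "stored") -> pd.DataFrame:
    """Per-sample responder calls and decision margins.

    ``mode='stored'`` applies the training scaler; ``mode='per_cohort'``
    re-estimates per-gene mean/sd within the given cohort (the external
    validation protocol, which removes cohort-wide location/scale
    shifts).  All panel genes must be present.
    """
    missing = [g for g in model.genes if g not in matrix.values.index]
    if missing:
        raise PredictionError(f"matrix lacks model genes: {missing}")
    log2 = matrix.log2().loc[model.genes]
    if mode == "stored":
        if model.scaler is None:
            raise PredictionError("model carries no scaler; use mode='per_cohort'")
        X = model.scaler.transform_log2(log2)
    elif mode == "per_cohort":
        sd = log2.std(axis=1, ddof=1).replace(0.0, 1.0)
        X = log2.sub(log2.mean(axis=1), axis=0).div(sd, axis=0).T
    else:
        raise ValueError(f"unknown mode {mode!r}")
    d = model.decision_values(X.to_numpy())
    return pd.DataFrame({
        "sample_id": list(matrix.sample_ids),
        "predicted_responder": d > 0,
        "decision_value": d,
    }).set_index("sample_id")


_PROTEIN_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z*]*)$")
_RAS_CODONS = {12, 13, 22, 61, 146}
_KRAS_CODONS = {12, 13}


def mutation_status_predictor(
    mutations: pd.DataFrame, samples: list[str], mode: str = "all_ras_raf"
) -> pd.Series:
    """Mutation-status baseline: predicted resistant iff a qualifying call.

    ``mode='kras_codon12_13'`` checks KRAS codons 12/13 only (the rule
    available for array cohorts with limited genotyping);
    ``mode='all_ras_raf'`` additionally checks KRAS/NRAS codons
    12, 13, 22, 61, 146 and BRAF V600E.  Unparseable protein changes
    raise a record-level warning and count as wild type.
    """
    if mode not in ("kras_codon12_13", "all_ras_raf"):
        raise ValueError(f"unknown mode {mode!r}")
    resistant: set[str] = set()
    for row in mutations.itertuples():
        gene = str(row.gene).upper()
        change = str(row.protein_change)
        m = _PROTEIN_RE.match(change.removeprefix("p."))
        if not m:
            warnings.warn(f"unparseable protein change {change!r} "
                          f"({row.sample_id}/{gene}); treated as wild type")
            continue
        codon = int(m.group(2))
        if mode == "kras_codon12_13":
            qualifies = gene == "KRAS" and codon in _KRAS_CODONS
        else:
            qualifies = (
                (gene in ("KRAS", "NRAS") and codon in _RAS_CODONS)
                or (gene == "BRAF" and m.group(1).upper() == "V"
                    and codon == 600 and m.group(3).upper() == "E")
            )
        if qualifies:
            resistant.add(str(row.sample_id))
    return pd.Series([s not in resistant for s in samples], index=samples,
                     name="predicted_responder")


@dataclass
class MiniClassifierTrainer:
    """End-to-end trainer: signature -> prune -> tune -> RFE -> select.

    Encapsulates the full pipeline so cross-validation can refit every
    trained step (differential expression, pruning, scaling, cost
    tuning, ranking, size selection) inside each training fold without
    leakage.  Resampling budgets default to simulation scale; raise
    them to 100/200 for a production run.
    """

    grid: tuple = COST_GRID_SMALL
    n_boot: int = 25
    n_resample: int = 50
    leave_out_fraction: float = 0.2
    candidate_sizes: tuple = (8, 12, 16, 20)
    top_m: int = 3
    fdr_max: float = 0.01
    min_abs_log2fc: float = 1.0
    min_mean_diff: float = 1.0
    model_system: str = "PDX"
    max_candidate_genes: int = 50
    fallback_genes: int = 10

    @classmethod
    def fast_cv(cls, **overrides) -> "MiniClassifierTrainer":
        """Minimal-budget trainer for use inside repeated CV folds."""
        params = dict(grid=COST_GRID_TINY, n_boot=10, n_resample=20,
                      candidate_sizes=(8, 12))
        params.update(overrides)
        return cls(**params)

    def fit(self, matrix: ExpressionMatrix, y: pd.Series, seed: int = 0):
        ya = y.loc[matrix.sample_ids].astype(bool)
        responders = list(ya.index[ya])
        resistant = list(ya.index[~ya])
        if len(responders) < 2 or len(resistant) < 2:
            raise TrainingError("need >=2 samples per class")
        de = differential_expression(matrix, responders, resistant)
        expressed = set(expression_filter(matrix, self.model_system))
        passed = de[(de["fdr"] <= self.fdr_max)
                    & (de["log2fc"].abs() >= self.min_abs_log2fc)
                    & (de["mean_diff"] >= self.min_mean_diff)]
        candidates = [g for g in passed.index if g in expressed]
        if len(candidates) > self.max_candidate_genes:
            order = passed.loc[candidates, "p"].sort_values(kind="stable")
            candidates = list(order.index[: self.max_candidate_genes])
        if len(candidates) < 2:
            # nothing passes (e.g. null labels): fall back to the top
            # genes by p-value so a model can still be produced
            candidates = list(de["p"].sort_values(kind="stable")
                              .index[: self.fallback_genes])
        log2 = matrix.log2().loc[candidates].T
        kept = prune_correlated(log2)
        X, scaler = preprocess_features(matrix, kept)
        rng = np.random.default_rng(seed)
        ranking = svm_rfe_rank(
            X, ya.to_numpy(), grid=self.grid, n_boot=self.n_boot,
            n_resample=self.n_resample,
            leave_out_fraction=self.leave_out_fraction,
            seed=int(rng.integers(2 ** 31)),
        )
        sizes = [k for k in self.candidate_sizes if k <= len(ranking.genes)]
        if not sizes:
            sizes = [len(ranking.genes)]
        _, model = select_model(
            ranking, X, ya.to_numpy(), grid=self.grid,
            candidate_sizes=sizes, top_m=self.top_m, n_boot=self.n_boot,
            seed=int(rng.integers(2 ** 31)), scaler=scaler,
        )
        return model
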