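"""Drug-response gene-signature discovery.

Differential expression between response groups is run in four setups
over the four-category response scale:

a. strong + moderate vs minor + resistant,
b. strong + moderate + minor vs resistant,
c. the N most sensitive vs the N least sensitive models
   (N = 20 for PDX, 10 for PDO),
d. a per-gene linear association of expression with the continuous
   phenotype (IC50 or T/C).

Group setups are filtered at FDR <= 0.01, |log2 FC| >= 1 and an RPKM
group-mean difference >= 1; the continuous setup at FDR <= 0.01 with a
per-gene dispersion (RPKM variance/mean) < 4.  The signature is the
union over setups, intersected with an expression floor (>= 1 RPKM in
at least five PDX or three PDO samples, mean >= 0.8 RPKM).

Also provides the robust variable-gene selector based on the quantile
absolute deviation QAD = P75(|x - median(x)|), the per-signature mean
pattern matrix (trimmed mean of log2, z-scored expression), and the
signed gene-ranking score used to compare matched PDX/PDO expression
profiles as pre-ranked enrichment input.

The two-group test defaults to Welch's t on log2(RPKM + 1) and is
pluggable, so a count-model backend can be substituted; every filter
threshold is implemented here regardless of the backend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

__all__ = [
    "Signature",
    "qad",
    "select_variable_genes",
    "expression_filter",
    "differential_expression",
    "glm_association",
    "assemble_signature",
    "mean_pattern_matrix",
    "pair_ranking_score",
]

PSEUDOCOUNT_RPKM = 0.1  # for fold changes; avoids infinite FC at zero


class DesignError(ValueError):
    pass


def qad(values) -> float:
    """Quantile absolute deviation: P75 of |x - median(x)|.

    A robust spread measure; linear-interpolation quantile, so
    qad([1,2,3,4,5]) == 2.0.  Translation-invariant and
    scale-equivariant; an all-equal vector yields 0.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("qad needs >=2 finite values")
    return float(np.quantile(np.abs(x - np.median(x)), 0.75))


def select_variable_genes(
    matrix: ExpressionMatrix,
    expression_floor: float = 0.5,
    min_samples: int = 3,
    top: float = 0.2,
) -> list[str]:
    """Most-variable genes by QAD on raw and log2 RPKM (intersection).

    A gene qualifies if it exceeds ``expression_floor`` RPKM in more
    than ``min_samples`` samples and ranks in the top ``top`` (fraction
    if <= 1, else count) by QAD under both the raw and the
    log2(RPKM + 1) transform.
    """
    raw = matrix.values
    expressed = (raw > expression_floor).sum(axis=1) > min_samples
    candidates = raw.index[expressed]
    if candidates.empty:
        warnings.warn("no gene passes the expression floor")
        return []
    raw_q = raw.loc[candidates].apply(qad, axis=1)
    log_q = matrix.log2().loc[candidates].apply(qad, axis=1)
    k = int(np.ceil(top * len(candidates))) if top <= 1 else int(top)
    k = max(1, min(k, len(candidates)))
    top_raw = set(raw_q.sort_values(ascending=False, kind="stable").index[:k])
    top_log = set(log_q.sort_values(ascending=False, kind="stable").index[:k])
    selected = sorted(top_raw & top_log)
    if not selected:
        warnings.warn("variable-gene intersection is empty")
    return selected


def expression_filter(
    matrix: ExpressionMatrix,
    model_system: str,
    min_rpkm: float = 1.0,
    min_samples: int | None = None,
    min_mean: float = 0.8,
) -> list[str]:
    """Low-expression filter: >= min_rpkm in enough samples, mean >= min_mean.

    The sample count defaults to five for PDX and three for PDO.
    """
    if min_samples is None:
        if model_system not in ("PDX", "PDO"):
            raise DesignError(f"unknown model system {model_system!r}")
        min_samples = 5 if model_system == "PDX" else 3
    vals = matrix.values
    keep = ((vals >= min_rpkm).sum(axis=1) >= min_samples) & (vals.mean(axis=1) >= min_mean)
    return list(vals.index[keep])


def _welch_t(log2_a: np.ndarray, log2_b: np.ndarray) -> np.ndarray:
    """Default two-group test: Welch's t on log2(RPKM + 1), per gene."""
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(log2_a, log2_b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    return np.where(np.isfinite(p), p, 1.0)


def differential_expression(
    matrix: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    test=None,
) -> pd.DataFrame:
    """Per-gene two-group differential expression statistics.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (on
    RPKM group means with a 0.1 pseudocount), ``mean_diff`` (absolute
    RPKM mean difference), ``p`` from the pluggable test on
    log2(RPKM + 1), ``fdr`` (Benjamini-Hochberg) and ``dispersion``
    (RPKM variance/mean across the tested samples).
    """
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise DesignError(f"groups overlap: {sorted(overlap)}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise DesignError("each group needs >=2 samples")
    test = test or _welch_t
    a = matrix.values[list(group_a)]
    b = matrix.values[list(group_b)]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = np.log2((mean_a + PSEUDOCOUNT_RPKM) / (mean_b + PSEUDOCOUNT_RPKM))
    mean_diff = (mean_a - mean_b).abs()
    p = test(np.log2(a.to_numpy() + 1.0), np.log2(b.to_numpy() + 1.0))
    fdr = multipletests(p, method="fdr_bh")[1]
    both = matrix.values[list(group_a) + list(group_b)]
    mean_all = both.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = both.var(axis=1, ddof=1) / mean_all
    dispersion = dispersion.where(mean_all > 0, 0.0)
    return pd.DataFrame({
        "log2fc": log2fc, "mean_diff": mean_diff, "p": p,
        "fdr": fdr, "dispersion": dispersion,
    }, index=matrix.values.index)


def glm_association(
    matrix: ExpressionMatrix,
    phenotype: pd.Series,
    dispersion_max: float = 4.0,
) -> pd.DataFrame:
    """Per-gene linear association of expression with a continuous phenotype.

    Fits log2(RPKM + 1) ~ phenotype by least squares per gene and tests
    the slope (t-test, n - 2 df).  Genes with RPKM dispersion
    (variance/mean) >= ``dispersion_max`` or with constant expression
    are excluded from the output; BH adjustment runs across the tested
    genes.  The fitted slope is reported as ``log2fc`` so downstream
    ordering has a comparable effect column.
    """
    samples = list(phenotype.index)
    missing = [s for s in samples if s not in matrix.values.columns]
    if missing:
        raise DesignError(f"phenotype samples absent from matrix: {missing}")
    y = phenotype.to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise DesignError("phenotype must be finite for all samples")
    if len(samples) < 5:
        raise DesignError("need >=5 samples")
    if np.std(y) == 0:
        raise DesignError("constant phenotype")

    vals = matrix.values[samples]
    log2 = np.log2(vals.to_numpy() + 1.0)
    n = len(samples)
    mean_all = vals.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = vals.var(axis=1, ddof=1) / mean_all
    dispersion = dispersion.where(mean_all > 0, 0.0)

    yc = y - y.mean()
    xc = log2 - log2.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum())
    const = sx == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.clip((xc @ yc) / (sx * sy), -1.0, 1.0)
        slope = (xc @ yc) / (yc @ yc)
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)

    keep = (~const) & (dispersion.to_numpy() < dispersion_max)
    out = pd.DataFrame({
        "log2fc": slope, "mean_diff": np.zeros(len(vals)), "p": p,
        "dispersion": dispersion.to_numpy(),
    }, index=vals.index)[keep]
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1] if len(out) else []
    return out[["log2fc", "mean_diff", "p", "fdr", "dispersion"]]


@dataclass
class Signature:
    """Ordered drug-response gene list with per-gene setup provenance."""

    drug: str
    model_system: str
    genes: list[str]
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)


def assemble_signature(
    setup_results: dict[str, pd.DataFrame],
    matrix: ExpressionMatrix,
    model_system: str,
    drug: str = "",
    fdr_max: float = 0.01,
    min_abs_log2fc: float = 1.0,
    min_mean_diff: float = 1.0,
) -> Signature:
    """Union of genes passing each setup's filters, expression-filtered.

    Group setups (a-c) require FDR <= ``fdr_max``, |log2 FC| >=
    ``min_abs_log2fc`` and RPKM mean difference >= ``min_mean_diff``;
    the continuous setup (d) requires FDR <= ``fdr_max`` only (its
    dispersion filter is applied inside :func:`glm_association`).
    Gene order is by descending best |log2fc| across setups, ties by
    gene id, so assembly is invariant to setup order.
    """
    if not setup_results:
        raise DesignError("need at least one setup result")
    expressed = set(expression_filter(matrix, model_system))
    provenance: dict[str, set[str]] = {}
    best_fc: dict[str, float] = {}
    for setup in sorted(setup_results):
        df = setup_results[setup]
        if setup == "d":
            passed = df.index[df["fdr"] <= fdr_max]
        else:
            passed = df.index[
                (df["fdr"] <= fdr_max)
                & (df["log2fc"].abs() >= min_abs_log2fc)
                & (df["mean_diff"] >= min_mean_diff)
            ]
        for g in passed:
            if g not in expressed:
                continue
            provenance.setdefault(g, set()).add(setup)
            fc = abs(float(df.loc[g, "log2fc"]))
            best_fc[g] = max(best_fc.get(g, 0.0), fc)
    genes = sorted(provenance, key=lambda g: (-best_fc[g], g))
    if not genes:
        warnings.warn(f"empty signature for {drug or 'drug'} ({model_system})")
    return Signature(drug=drug, model_system=model_system,
                     genes=genes, provenance=provenance)


def mean_pattern_matrix(
    matrix: ExpressionMatrix,
    signatures: dict[str, list[str]],
    trim: float = 0.25,
    reference_stats: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Samples x signatures matrix of trimmed-mean z-scored expression.

    Each gene's log2(RPKM + 1) profile is z-scored across samples (or
    against stored per-gene ``reference_stats`` with columns ``mean``
    and ``sd``, for projecting model cohorts onto a patient cohort);
    each (sample, signature) entry is the trimmed mean over the
    signature's genes, cutting ``trim`` from each tail.  Duplicate
    genes within a signature are collapsed; signatures with no gene in
    the matrix yield a NaN column with a warning.
    """
    log2 = matrix.log2()
    if reference_stats is not None:
        common = log2.index.intersection(reference_stats.index)
        log2 = log2.loc[common]
        mean = reference_stats.loc[common, "mean"]
        sd = reference_stats.loc[common, "sd"].replace(0.0, np.nan)
    else:
        mean = log2.mean(axis=1)
        sd = log2.std(axis=1, ddof=1).replace(0.0, np.nan)
    z = log2.sub(mean, axis=0).div(sd, axis=0).dropna()

    cols = {}
    for name, genes in signatures.items():
        present = [g for g in dict.fromkeys(genes) if g in z.index]
        if not present:
            warnings.warn(f"signature {name!r} has no gene in the matrix")
            cols[name] = pd.Series(np.nan, index=log2.columns)
            continue
        sub = z.loc[present]
        cols[name] = pd.Series(
            stats.trim_mean(sub.to_numpy(), proportiontocut=trim, axis=0),
            index=log2.columns,
        )
    return pd.DataFrame(cols)


def pair_ranking_score(
    pdx_expr: pd.Series,
    pdo_expr: pd.Series,
    mode: str = "zero_discordant",
) -> pd.Series:
    """Signed per-gene score ranking a matched PDX/PDO expression pair.

    Combines the fold change f = log2((x + 0.1) / (y + 0.1)) on RPKM
    and the difference d = log2(x + 1) - log2(y + 1) via their
    geometric mean r = sign(f) * sqrt(|f| * |d|).  With the default
    ``zero_discordant`` rule, genes where f and d disagree in sign
    score 0; the ``signed`` alternative keeps sign(f) regardless.
    Returned sorted descending — a complete ranking suitable as
    pre-ranked enrichment input.
    """
    if not pdx_expr.index.equals(pdo_expr.index):
        common = pdx_expr.index.intersection(pdo_expr.index)
        pdx_expr, pdo_expr = pdx_expr[common], pdo_expr[common]
    x = pdx_expr.to_numpy(dtype=float)
    y = pdo_expr.to_numpy(dtype=float)
    f = np.log2((x + PSEUDOCOUNT_RPKM) / (y + PSEUDOCOUNT_RPKM))
    d = np.log2(x + 1.0) - np.log2(y + 1.0)
    mag = np.sqrt(np.abs(f) * np.abs(d))
    if mode == "zero_discordant":
        r = np.where(np.sign(f) == np.sign(d), np.sign(f) * mag, 0.0)
    elif mode == "signed":
        r = np.sign(f) * mag
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.Series(r, index=pdx_expr.index).sort_values(
        ascending=False, kind="stable")
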