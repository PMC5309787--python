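"""Synthetic preclinical cohorts with known ground truth.

Every downstream stage (dose-response fitting, xenograft scoring,
signature discovery, classifier training, evaluation) is exercised on
cohorts produced here, so the generator states its statistical
assumptions explicitly:

* expression: log2(RPKM + 1) of each gene is Normal(mu_g, noise_sd)
  with gene baselines mu_g drawn uniformly from a configured log2
  range; responder/resistant differential genes are planted by shifting
  the responder-group mean by a configured log2 fold change;
* correlated gene pairs: a partner gene is the source gene's signal
  plus independent Normal noise calibrated so the expected sample
  correlation hits a target (the partner gets the lower baseline mean,
  so the pruning direction is known in truth);
* a configured fraction of genes is forced below 1 RPKM mean to
  exercise low-expression filters;
* dose-response: replicate percent-inhibition readings on a 4PL curve
  with additive Gaussian noise;
* tumour growth: exponential growth with multiplicative log-normal
  noise; treatment scales the growth rate down by a fractional effect;
  calliper (length, width) pairs are emitted under a fixed
  length = 1.2 * width convention so volumes round-trip exactly;
* response labels: thresholding of a standardized score over the
  planted genes (signature link) and/or forced resistance for
  KRAS/BRAF-mutant samples (mutation link), with matched endpoint T/C
  values (responders <= 25%, resistant > 25%).

All outputs are bit-reproducible given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import DoseResponseCurve, four_parameter_logistic
from .matrix import ExpressionMatrix
from .xenograft import GrowthSeries, TumorMeasurement, categorize_tc

__all__ = [
    "SyntheticConfig",
    "CohortTruth",
    "generate_expression_matrix",
    "generate_dose_response",
    "generate_growth_series",
    "generate_cohort",
]


class ConfigurationError(ValueError):
    """Raised when a synthetic-cohort configuration violates its bounds."""


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic cohort.

    Defaults mirror the training setup the pipeline targets: 14
    responding vs 34 resistant models, a few hundred genes with ten
    planted differential genes at |log2 FC| = 2, five highly correlated
    pairs, and unit log2-scale noise.
    """

    n_responders: int = 14
    n_resistant: int = 34
    n_genes: int = 200
    n_informative: int = 10
    effect_log2fc: float = 2.0
    n_corr_pairs: int = 5
    corr_target: float = 0.9
    baseline_log2_mean_range: tuple[float, float] = (2.0, 8.0)
    noise_sd: float = 1.0
    frac_low_expressed: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_responders", "n_resistant", "n_genes",
                     "n_informative", "n_corr_pairs"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_informative > self.n_genes:
            raise ConfigurationError(
                f"n_informative ({self.n_informative}) exceeds n_genes ({self.n_genes})"
            )
        if 2 * self.n_corr_pairs > self.n_genes:
            raise ConfigurationError(
                f"2*n_corr_pairs ({2 * self.n_corr_pairs}) exceeds n_genes ({self.n_genes})"
            )
        if not (0.0 <= self.corr_target < 1.0):
            raise ConfigurationError("corr_target must lie in [0, 1)")
        if not (0.0 <= self.frac_low_expressed <= 1.0):
            raise ConfigurationError("frac_low_expressed must lie in [0, 1]")
        lo, hi = self.baseline_log2_mean_range
        if hi < lo:
            raise ConfigurationError("baseline_log2_mean_range must be (lo, hi)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.n_responders + self.n_resistant


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort."""

    labels: pd.Series  # bool per sample: True = responder
    informative_genes: list[str]
    corr_pairs: list[tuple[str, str]]
    mutation_truth: dict[str, list[tuple[str, str]]] = field(default_factory=dict)


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:03d}" for i in range(n)]


def generate_expression_matrix(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, CohortTruth]:
    """Draw a genes x samples RPKM matrix with planted structure.

    Layout: the first ``n_informative`` genes are differential
    (responder mean shifted by ``effect_log2fc`` on the log2 scale), the
    next ``2 * n_corr_pairs`` genes host the correlated pairs, and the
    low-expression mask is drawn from the remaining null genes.
    """
    rng = np.random.default_rng(config.seed)
    n_s, n_g = config.n_samples, config.n_genes
    genes = _gene_ids(n_g)
    samples = _sample_ids(n_s)
    responder = np.zeros(n_s, dtype=bool)
    responder[: config.n_responders] = True

    lo, hi = config.baseline_log2_mean_range
    mu = rng.uniform(lo, hi, size=n_g)

    pair_src = list(range(config.n_informative,
                          config.n_informative + config.n_corr_pairs))
    pair_dst = list(range(config.n_informative + config.n_corr_pairs,
                          config.n_informative + 2 * config.n_corr_pairs))

    # Low-expression genes: mean RPKM < 1, i.e. E[2^x] < 2 for
    # x ~ N(mu, sd) with E[2^x] = 2^mu * exp((sd*ln2)^2 / 2).
    reserved = set(range(config.n_informative)) | set(pair_src) | set(pair_dst)
    free = [i for i in range(n_g) if i not in reserved]
    n_low = min(int(round(config.frac_low_expressed * n_g)), len(free))
    low_idx = rng.choice(free, size=n_low, replace=False) if n_low else np.array([], int)
    sd_ln = config.noise_sd * np.log(2.0)
    mu_bound = 1.0 - (sd_ln ** 2 / 2.0) / np.log(2.0)
    mu_low_hi = max(0.1, 0.9 * mu_bound)
    mu[low_idx] = rng.uniform(0.02, mu_low_hi, size=n_low)

    x = mu[:, None] + rng.normal(0.0, config.noise_sd, size=(n_g, n_s))
    x[: config.n_informative, responder] += config.effect_log2fc

    # Correlated partners: shared latent signal + calibrated noise so the
    # expected Pearson correlation equals corr_target.
    pairs: list[tuple[str, str]] = []
    for src, dst in zip(pair_src, pair_dst):
        # partner keeps the lower baseline mean, but stays high enough
        # that the RPKM >= 0 floor cannot censor its low tail
        mu[dst] = max(mu[src] - 1.0, lo)
        rho = config.corr_target
        if rho > 0 and config.noise_sd > 0:
            # corr(src, dst) = sd / sqrt(sd^2 + sigma_e^2) = rho
            sigma_e = config.noise_sd * np.sqrt(1.0 / rho ** 2 - 1.0)
            x[dst] = mu[dst] + (x[src] - mu[src]) + rng.normal(0.0, sigma_e, size=n_s)
        else:
            x[dst] = mu[dst] + rng.normal(0.0, config.noise_sd, size=n_s)
        pairs.append((genes[src], genes[dst]))

    rpkm = np.clip(np.exp2(x) - 1.0, 0.0, None)
    # low-expression genes are forced below 1 RPKM mean even when the
    # sampling draw lands high
    for i in low_idx:
        m = rpkm[i].mean()
        if m >= 1.0:
            rpkm[i] *= 0.9 / m
    values = pd.DataFrame(rpkm, index=genes, columns=samples)
    truth = CohortTruth(
        labels=pd.Series(responder, index=samples, name="responder"),
        informative_genes=genes[: config.n_informative],
        corr_pairs=pairs,
    )
    return ExpressionMatrix(values), truth


def generate_dose_response(
    ic50_true: float,
    emax_true: float,
    hill: float,
    concentrations: np.ndarray,
    noise_sd: float = 0.0,
    replicates: int = 2,
    seed: int = 0,
    drug: str = "drug",
    model_id: str = "model",
) -> DoseResponseCurve:
    """Simulate replicate percent-inhibition readings on a 4PL curve.

    The curve bottom is 0 and the top asymptote is chosen so that the
    noise-free inhibition at the highest tested concentration equals
    ``emax_true``.  Noise is additive Normal(0, noise_sd) per replicate.
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ConfigurationError("concentrations must be strictly positive")
    if np.unique(conc).size < 4:
        raise ConfigurationError("need >=4 distinct concentrations")
    if replicates < 1:
        raise ConfigurationError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    c_max = conc.max()
    top = emax_true * (1.0 + (ic50_true / c_max) ** hill)
    mean = four_parameter_logistic(conc, 0.0, top, ic50_true, hill)
    noise = rng.normal(0.0, noise_sd, size=(conc.size, replicates)) if noise_sd > 0 \
        else np.zeros((conc.size, replicates))
    return DoseResponseCurve(
        drug=drug, model_id=model_id, concentrations=conc,
        inhibition=mean[:, None] + noise,
    )


def _volume_to_calliper(volume: float) -> tuple[float, float]:
    # V = length * width^2 / 2 with length = 1.2 * width  =>  V = 0.6 w^3
    width = (volume / 0.6) ** (1.0 / 3.0)
    return 1.2 * width, width


def generate_growth_series(
    n_animals: int,
    v0: float,
    growth_rate: float,
    treatment_effect: float,
    days: list[float],
    noise_cv: float = 0.0,
    seed: int = 0,
    drug: str = "drug",
) -> list[GrowthSeries]:
    """Simulate exponential tumour growth for a treated and a control arm.

    Control volumes follow v0 * exp(growth_rate * t); treatment scales
    the growth rate by (1 - treatment_effect).  Multiplicative
    log-normal noise with coefficient of variation ``noise_cv`` is
    applied per measurement.  Measurements are emitted as calliper
    (length, width) pairs with length = 1.2 * width so that the volume
    formula V = length * width^2 / 2 recovers the simulated volume.
    """
    if n_animals < 1:
        raise ConfigurationError("need >=1 animal per arm")
    if v0 <= 0:
        raise ConfigurationError("v0 must be positive")
    if not days or any(b <= a for a, b in zip(days, days[1:])):
        raise ConfigurationError("days must be nonempty and ascending")
    if not (0.0 <= treatment_effect <= 1.0):
        raise ConfigurationError("treatment_effect must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    t = np.asarray(days, dtype=float)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv ** 2))
        ln_mu = -sigma ** 2 / 2.0  # unit-mean log-normal
    series: list[GrowthSeries] = []
    for arm, rate in (("control", growth_rate),
                      ("treated", growth_rate * (1.0 - treatment_effect))):
        for a in range(n_animals):
            vols = v0 * np.exp(rate * t)
            if noise_cv > 0:
                vols = vols * np.exp(rng.normal(ln_mu, sigma, size=t.size))
            meas = []
            for day, vol in zip(t, vols):
                length, width = _volume_to_calliper(vol)
                meas.append(TumorMeasurement(day=float(day), length=length, width=width))
            series.append(GrowthSeries(f"{arm}_{a:02d}", arm, drug, meas))
    return series


_QUALIFYING_MUTATIONS = [("KRAS", "G12D"), ("KRAS", "G13D"),
                         ("NRAS", "Q61K"), ("BRAF", "V600E")]


def generate_cohort(
    config: SyntheticConfig,
    response_link: str = "signature",
    drug: str = "drugX",
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Full cohort: expression, response table, mutation table, truth.

    Response labels come from the configured link:

    * ``signature`` — threshold a standardized linear score over the
      planted differential genes so that exactly ``n_responders``
      samples are called responders;
    * ``mutation`` — qualifying KRAS/NRAS/BRAF mutations are assigned
      to ``n_resistant`` samples and mutants are labelled resistant;
    * ``mixed`` — signature labels, with mutations planted in a subset
      of the resistant samples (mutants are always resistant).

    The response table carries matched endpoint T/C values: responders
    drawn uniformly from (2, 25], resistant from (25, 120].
    """
    if config.n_responders == 0 or config.n_resistant == 0:
        raise ConfigurationError(
            "degenerate cohort: classifier training needs both classes"
        )
    if response_link not in ("signature", "mutation", "mixed"):
        raise ConfigurationError(f"unknown response link {response_link!r}")

    matrix, truth = generate_expression_matrix(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    samples = matrix.sample_ids
    n = len(samples)

    if response_link in ("signature", "mixed"):
        log2 = matrix.log2().loc[truth.informative_genes]
        z = log2.sub(log2.mean(axis=1), axis=0).div(
            log2.std(axis=1, ddof=1).replace(0.0, 1.0), axis=0)
        score = z.mean(axis=0)
        if config.effect_log2fc == 0:
            # no planted effect: the score carries no label signal, so
            # labels are an independent random draw (permutation null)
            order = rng.permutation(n)
        else:
            order = np.argsort(-score.to_numpy(), kind="stable")
        responder = np.zeros(n, dtype=bool)
        responder[order[: config.n_responders]] = True
    else:
        responder = np.zeros(n, dtype=bool)
        responder[rng.choice(n, size=config.n_responders, replace=False)] = True

    labels = pd.Series(responder, index=samples, name="responder")

    # Mutations: planted only in resistant samples so the mutation link
    # (mutant => resistant) holds by construction.
    mut_rows = []
    mutation_truth: dict[str, list[tuple[str, str]]] = {s: [] for s in samples}
    if response_link in ("mutation", "mixed"):
        resistant_samples = [s for s in samples if not labels[s]]
        if response_link == "mutation":
            carriers = resistant_samples
        else:
            k = max(1, int(round(0.6 * len(resistant_samples))))
            carriers = sorted(rng.choice(resistant_samples, size=k, replace=False))
        for s in carriers:
            gene, change = _QUALIFYING_MUTATIONS[
                int(rng.integers(len(_QUALIFYING_MUTATIONS)))]
            mut_rows.append({"sample_id": s, "gene": gene, "protein_change": change})
            mutation_truth[s].append((gene, change))
    mutations = pd.DataFrame(mut_rows, columns=["sample_id", "gene", "protein_change"])

    tc = np.where(
        responder,
        rng.uniform(2.0, 25.0, size=n),
        rng.uniform(25.0 + 1e-9, 120.0, size=n),
    )
    response = pd.DataFrame({
        "model_id": samples,
        "drug": drug,
        "tc_percent": tc,
        "tc_category": [categorize_tc(v).name for v in tc],
        "responder": responder,
    })

    truth.labels = labels
    truth.mutation_truth = mutation_truth
    return matrix, response, mutations, truth
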