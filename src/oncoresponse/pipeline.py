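"""Top-level pipeline: simulate -> signature -> train -> evaluate.

Binds the analysis stages in order on a configured cohort, writing
every stage artifact (expression TSV, response/mutation CSV, signature
gene list, model JSON, evaluation report) plus a manifest with input
checksums, seeds and settings so a rerun with the same config
reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classifier import (
    COST_GRID_DEFAULT,
    COST_GRID_SMALL,
    COST_VALUES_5FU,
    FeatureScaler,
    MiniClassifierTrainer,
    SvmModel,
    mutation_status_predictor,
)
from .evaluation import (
    compare_predictors,
    confusion_and_metrics,
    repeated_cross_validation,
)
from .matrix import ExpressionMatrix, write_expression_tsv
from .signatures import (
    Signature,
    assemble_signature,
    differential_expression,
    glm_association,
)
from .synthetic import SyntheticConfig, generate_cohort

__all__ = [
    "RunConfig",
    "run_pipeline",
    "derive_drug_signature",
    "save_model",
    "load_model",
    "cost_grid",
]

_GRIDS = {
    "default": COST_GRID_DEFAULT,
    "5fu": tuple((a, b) for a in COST_VALUES_5FU for b in COST_VALUES_5FU),
    "small": COST_GRID_SMALL,
}


def cost_grid(name: str) -> tuple:
    try:
        return _GRIDS[name]
    except KeyError:
        raise ValueError(f"unknown cost grid {name!r}; "
                         f"choose from {sorted(_GRIDS)}") from None


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML-loadable).

    ``preset`` selects the tuning defaults: 'cetuximab' (default grid,
    top_m=3), '5fu' (grid extended with 0.007, top_m=11) or 'synthetic'
    (reduced grid and resampling for simulation-scale runs).
    """

    preset: str = "synthetic"
    seed: int = 0
    cohort: dict = field(default_factory=dict)
    response_link: str = "signature"
    model_system: str = "PDX"
    cv_repeats: int = 10
    cv_folds: int = 10
    n_boot: int | None = None
    n_resample: int | None = None
    grid: str | None = None
    candidate_sizes: tuple = (8, 12, 16, 20)
    top_m: int | None = None

    _PRESETS = {
        "cetuximab": {"grid": "default", "top_m": 3, "n_boot": 100, "n_resample": 200},
        "5fu": {"grid": "5fu", "top_m": 11, "n_boot": 100, "n_resample": 200},
        "synthetic": {"grid": "small", "top_m": 3, "n_boot": 25, "n_resample": 50},
    }

    def __post_init__(self) -> None:
        if self.preset not in self._PRESETS:
            raise ConfigError(f"unknown preset {self.preset!r}")
        defaults = self._PRESETS[self.preset]
        for key, value in defaults.items():
            if getattr(self, key) is None:
                setattr(self, key, value)
        if self.cv_repeats < 1 or self.cv_folds < 2:
            raise ConfigError("cv_repeats >= 1 and cv_folds >= 2 required")
        cost_grid(self.grid)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__) - {"_PRESETS"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "candidate_sizes" in raw:
            raw["candidate_sizes"] = tuple(raw["candidate_sizes"])
        return cls(**raw)

    def trainer(self) -> MiniClassifierTrainer:
        return MiniClassifierTrainer(
            grid=cost_grid(self.grid), n_boot=self.n_boot,
            n_resample=self.n_resample,
            candidate_sizes=tuple(self.candidate_sizes), top_m=self.top_m,
            model_system=self.model_system,
        )


def derive_drug_signature(
    matrix: ExpressionMatrix,
    response: pd.DataFrame,
    model_system: str = "PDX",
    drug: str = "",
) -> Signature:
    """Run all four differential-expression setups and assemble.

    ``response`` needs columns model_id, tc_category (or the analogous
    IC50-based category) and a continuous phenotype column
    (``tc_percent`` or ``ic50``) for the linear-association setup.
    Setup c contrasts the 20 (PDX) or 10 (PDO) most vs least sensitive
    models.
    """
    resp = response.set_index("model_id")
    samples = [s for s in matrix.sample_ids if s in resp.index]
    resp = resp.loc[samples]
    cat = resp["tc_category"].astype(str)
    pheno_col = "tc_percent" if "tc_percent" in resp.columns else "ic50"
    pheno = resp[pheno_col].astype(float)

    sensitive = cat.isin(["STRONG", "MODERATE"])
    non_resistant = cat.isin(["STRONG", "MODERATE", "MINOR"])
    n_extreme = 20 if model_system == "PDX" else 10
    order = pheno.sort_values(kind="stable").index
    n_extreme = min(n_extreme, len(order) // 2)

    setups: dict[str, pd.DataFrame] = {}
    mat = matrix.subset_samples(samples)
    if sensitive.sum() >= 2 and (~sensitive).sum() >= 2:
        setups["a"] = differential_expression(
            mat, list(cat.index[sensitive]), list(cat.index[~sensitive]))
    if non_resistant.sum() >= 2 and (~non_resistant).sum() >= 2:
        setups["b"] = differential_expression(
            mat, list(cat.index[non_resistant]), list(cat.index[~non_resistant]))
    if n_extreme >= 2:
        setups["c"] = differential_expression(
            mat, list(order[:n_extreme]), list(order[-n_extreme:]))
    if pheno.nunique() > 1 and len(pheno) >= 5:
        setups["d"] = glm_association(mat, pheno)
    return assemble_signature(setups, mat, model_system, drug=drug)


def save_model(model: SvmModel, path: str | Path, metadata: dict | None = None) -> None:
    """Serialize an SVM panel to JSON (genes, weights, costs, scaler)."""
    payload = {
        "genes": model.genes,
        "w": [float(v) for v in model.w],
        "b": model.b,
        "c_resis": model.c_resis,
        "c_resp": model.c_resp,
        "positive_class": model.positive_class,
        "scaler": (
            {g: [float(model.scaler.mean[g]), float(model.scaler.sd[g])]
             for g in model.genes}
            if model.scaler is not None else None
        ),
        "metadata": metadata or {},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_model(path: str | Path) -> SvmModel:
    payload = json.loads(Path(path).read_text())
    scaler = None
    if payload.get("scaler"):
        mean = pd.Series({g: ms[0] for g, ms in payload["scaler"].items()})
        sd = pd.Series({g: ms[1] for g, ms in payload["scaler"].items()})
        scaler = FeatureScaler(mean=mean.loc[payload["genes"]],
                               sd=sd.loc[payload["genes"]])
    return SvmModel(
        genes=list(payload["genes"]), w=np.array(payload["w"], dtype=float),
        b=float(payload["b"]), c_resis=float(payload["c_resis"]),
        c_resp=float(payload["c_resp"]), scaler=scaler,
        positive_class=payload.get("positive_class", "responder"),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute simulate -> signature -> train -> evaluate and write artifacts.

    Returns the manifest dictionary (also written to manifest.json).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_cfg = SyntheticConfig(**{**config.cohort, "seed": config.seed})
    matrix, response, mutations, truth = generate_cohort(
        cohort_cfg, response_link=config.response_link)

    write_expression_tsv(matrix, out / "expression.tsv")
    response.to_csv(out / "response.csv", index=False)
    mutations.to_csv(out / "mutations.csv", index=False)
    (out / "truth.json").write_text(json.dumps({
        "labels": {s: bool(v) for s, v in truth.labels.items()},
        "informative_genes": truth.informative_genes,
        "corr_pairs": truth.corr_pairs,
    }, indent=2, sort_keys=True))

    signature = derive_drug_signature(matrix, response,
                                      model_system=config.model_system)
    (out / "signature.txt").write_text("\n".join(signature.genes) + "\n")
    (out / "signature.json").write_text(json.dumps({
        "genes": signature.genes,
        "provenance": {g: sorted(v) for g, v in signature.provenance.items()},
    }, indent=2, sort_keys=True))

    trainer = config.trainer()
    y = truth.labels
    rng = np.random.default_rng(config.seed)
    model = trainer.fit(matrix, y, seed=int(rng.integers(2 ** 31)))
    save_model(model, out / "model.json", metadata={
        "seed": config.seed, "preset": config.preset, "grid": config.grid,
        "n_boot": config.n_boot, "n_resample": config.n_resample,
        "top_m": config.top_m,
    })

    cv_report, cv_table = repeated_cross_validation(
        matrix, y, trainer, folds=config.cv_folds, repeats=config.cv_repeats,
        seed=int(rng.integers(2 ** 31)))
    cv_table.to_csv(out / "cv_repeats.csv", index=False)
    mut_pred = mutation_status_predictor(mutations, matrix.sample_ids,
                                         mode="all_ras_raf")
    mut_report = confusion_and_metrics(y.loc[matrix.sample_ids],
                                       mut_pred.loc[matrix.sample_ids])
    comparison = compare_predictors(
        confusion_and_metrics(
            y.loc[matrix.sample_ids],
            # refit-model predictions on the training cohort (descriptive)
            (matrix.log2().loc[model.genes].pipe(
                lambda l: model.scaler.transform_log2(l)).to_numpy() @ model.w
             + model.b) > 0,
        ),
        mut_report,
    )
    comparison.to_csv(out / "classifier_vs_mutation.csv")
    (out / "evaluation.json").write_text(json.dumps({
        "cv": asdict(cv_report),
        "mutation_status": asdict(mut_report),
    }, indent=2, sort_keys=True))

    try:
        pkg_version = version("oncoresponse")
    except PackageNotFoundError:
        pkg_version = "unknown"
    manifest = {
        "version": pkg_version,
        "seed": config.seed,
        "preset": config.preset,
        "settings": {
            "grid": config.grid, "n_boot": config.n_boot,
            "n_resample": config.n_resample, "top_m": config.top_m,
            "cv_repeats": config.cv_repeats, "cv_folds": config.cv_folds,
            "response_link": config.response_link,
            "cohort": asdict(cohort_cfg),
        },
        "artifacts": {
            p.name: _sha256(p) for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
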