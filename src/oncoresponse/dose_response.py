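"""Organoid (PDO) in-vitro drug sensitivity.

Implements plate normalization against vehicle (max signal) and
staurosporine (min signal) controls, four-parameter logistic (4PL)
fitting of percent-inhibition curves, the relative IC50 / Emax summary,
the four-category response calls, and Spearman drug-drug sensitivity
correlation.

The 4PL model on concentration ``c`` is::

    y(c) = bottom + (top - bottom) / (1 + (ic50 / c) ** hill)

where ``ic50`` is the relative IC50 (curve inflection), not the
absolute-50% crossing.  Fitting is done on the log10-concentration
scale over replicate means.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ResponseCategory",
    "DoseResponseCurve",
    "DoseResponseFit",
    "percent_inhibition",
    "serial_dilution_series",
    "four_parameter_logistic",
    "fit_four_parameter_logistic",
    "categorize_pdo",
    "fit_plate_table",
    "drug_correlation_matrix",
    "PDO_IC50_BOUNDS_UM",
    "CETUXIMAB_LOG_BOUNDS",
]


class PlateError(ValueError):
    """Raised when plate controls are unusable."""


class DesignError(ValueError):
    """Raised when an assay design precondition is violated."""


class ResponseCategory(enum.IntEnum):
    """Ordered four-level drug-response scale (lower = more sensitive)."""

    STRONG = 0
    MODERATE = 1
    MINOR = 2
    RESISTANT = 3

    def rank_distance(self, other: "ResponseCategory") -> int:
        return abs(int(self) - int(other))


# Relative IC50 category boundaries (uM), sensitive side inclusive.
PDO_IC50_BOUNDS_UM = (0.0361, 0.4277, 5.0656)
# Cetuximab categories are defined on log(IC50); the printed boundaries
# leave (-5.777, -4.703] unassigned, which we fold into MODERATE.
CETUXIMAB_LOG_BOUNDS = (-5.777, -3.63, -1.483)


def percent_inhibition(reading: float, max_ctrl: float, min_ctrl: float) -> float:
    """Normalize a luminescence reading to percent growth inhibition.

    ``max_ctrl`` is the mean of vehicle (DMSO) wells, ``min_ctrl`` the
    mean of 5 uM staurosporine kill-control wells.  Vehicle maps to 0%,
    staurosporine to 100%; values outside [0, 100] are permitted
    (biological overshoot).
    """
    if not max_ctrl > min_ctrl:
        raise PlateError(
            f"max control ({max_ctrl}) must exceed min control ({min_ctrl})"
        )
    return 100.0 * (max_ctrl - reading) / (max_ctrl - min_ctrl)


def serial_dilution_series(top: float, factor: float, n_points: int) -> np.ndarray:
    """Concentrations of a serial dilution: top, top/factor, ...

    Matches assay plate layouts such as a ten-point 1:3 series from
    60 uM down to 3.05 nM.
    """
    if top <= 0:
        raise DesignError("top concentration must be positive")
    if factor <= 1:
        raise DesignError("dilution factor must exceed 1")
    if n_points < 1:
        raise DesignError("need at least one point")
    return top / factor ** np.arange(n_points, dtype=float)


@dataclass
class DoseResponseCurve:
    """Per-(model, drug) normalized inhibition data.

    ``concentrations`` are uM, strictly positive, with at least four
    distinct values.  ``inhibition`` has shape (n_concentrations,
    n_replicates) in percent inhibition.
    """

    drug: str
    model_id: str
    concentrations: np.ndarray
    inhibition: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.inhibition = np.atleast_2d(np.asarray(self.inhibition, dtype=float))
        if self.inhibition.shape[0] != self.concentrations.size:
            self.inhibition = self.inhibition.T
        if np.any(self.concentrations <= 0):
            raise DesignError("concentrations must be strictly positive")
        if np.unique(self.concentrations).size < 4:
            raise DesignError("need >=4 distinct concentrations")
        if self.inhibition.shape[0] != self.concentrations.size:
            raise DesignError("inhibition rows must match concentrations")
        if not np.all(np.isfinite(self.inhibition)):
            raise ValueError("non-finite inhibition readings")

    @property
    def replicate_means(self) -> np.ndarray:
        return self.inhibition.mean(axis=1)


@dataclass
class DoseResponseFit:
    """4PL fit summary: relative IC50 (uM), Emax (%), slope, asymptotes."""

    ic50: float
    emax: float
    hill: float
    top: float
    bottom: float
    converged: bool
    ic50_censored: str = "none"  # none | above_range | below_range
    sse: float = field(default=float("nan"), repr=False)


def four_parameter_logistic(
    c: np.ndarray, bottom: float, top: float, ic50: float, hill: float
) -> np.ndarray:
    """Evaluate the 4PL curve at concentrations ``c``."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ic50 / c) ** hill)


def _residuals(params: np.ndarray, log_c: np.ndarray, y: np.ndarray) -> np.ndarray:
    bottom, top, log_ic50, hill = params
    pred = bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ic50 - log_c)))
    return pred - y


def fit_four_parameter_logistic(curve: DoseResponseCurve) -> DoseResponseFit:
    """Least-squares 4PL fit on replicate means, log10-concentration scale.

    Emax is the mean observed inhibition at the maximum concentration
    regardless of fit quality.  A flat curve (response span under 10
    percentage points) or an optimizer failure yields ``converged=False``
    with the IC50 censored above the tested range, which downstream
    categorization treats as resistant.
    """
    order = np.argsort(curve.concentrations)
    conc = curve.concentrations[order]
    y = curve.replicate_means[order]
    emax = float(y[-1])
    log_c = np.log10(conc)

    if y.max() - y.min() < 10.0:
        return DoseResponseFit(
            ic50=float("nan"), emax=emax, hill=float("nan"),
            top=float(y.max()), bottom=float(y.min()),
            converged=False, ic50_censored="above_range",
        )

    lo = np.array([-100.0, -100.0, log_c[0] - 4.0, 0.05])
    hi = np.array([200.0, 250.0, log_c[-1] + 4.0, 10.0])
    x0 = np.array([y.min(), y.max(), 0.5 * (log_c[0] + log_c[-1]), 1.0])
    rng = np.random.default_rng(0)  # jittered restarts, fixed for determinism
    starts = [x0]
    for _ in range(5):
        jitter = rng.normal(0, [5.0, 5.0, 0.5, 0.3])
        starts.append(np.clip(x0 + jitter, lo + 1e-9, hi - 1e-9))

    best = None
    for start in starts:
        try:
            res = least_squares(
                _residuals, start, args=(log_c, y), bounds=(lo, hi), method="trf"
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res

    if best is None:
        return DoseResponseFit(
            ic50=float("nan"), emax=emax, hill=float("nan"),
            top=float(y.max()), bottom=float(y.min()),
            converged=False, ic50_censored="above_range",
        )

    bottom, top, log_ic50, hill = best.x
    ic50 = float(10.0 ** log_ic50)
    censored = "none"
    if ic50 > conc[-1]:
        censored = "above_range"
    elif ic50 < conc[0]:
        censored = "below_range"
    return DoseResponseFit(
        ic50=ic50, emax=emax, hill=float(hill), top=float(top),
        bottom=float(bottom), converged=True, ic50_censored=censored,
        sse=float(2.0 * best.cost),
    )


def categorize_pdo(fit: DoseResponseFit, scale: str = "micromolar") -> ResponseCategory:
    """Map a fitted relative IC50 to the four-category response scale.

    Boundaries are inclusive on the sensitive side.  Unconverged or
    above-range-censored fits are called RESISTANT so that every
    screened model receives a category.
    """
    if not fit.converged or fit.ic50_censored == "above_range" or not np.isfinite(fit.ic50):
        return ResponseCategory.RESISTANT
    if scale == "micromolar":
        value = fit.ic50
        bounds = PDO_IC50_BOUNDS_UM
    elif scale == "log_units":
        value = np.log10(fit.ic50)
        bounds = CETUXIMAB_LOG_BOUNDS
    else:
        raise ValueError(f"unknown scale {scale!r}")
    for level, bound in zip(
        (ResponseCategory.STRONG, ResponseCategory.MODERATE, ResponseCategory.MINOR),
        bounds,
    ):
        if value <= bound:
            return level
    return ResponseCategory.RESISTANT


def fit_plate_table(table: pd.DataFrame, antibody_mw: float | None = None) -> pd.DataFrame:
    """Fit every (model, drug) curve in a long-format plate table.

    Expected columns: model_id, drug, concentration, replicate, and
    either ``inhibition`` (pre-normalized %) or ``reading`` (raw
    luminescence, with control wells flagged by ``well_type`` in
    {max_ctrl, min_ctrl} and missing concentration).  An optional
    ``unit`` column may declare ng/ml, converted to uM via
    ``antibody_mw`` (g/mol) — the antibody case.  Returns one row per
    curve with ic50_uM, emax_pct, hill, category and censoring.
    """
    df = table.copy()
    if "unit" in df.columns:
        ngml = df["unit"].astype(str).str.lower().isin(("ng/ml", "ng per ml"))
        if ngml.any():
            if antibody_mw is None:
                raise DesignError("ng/ml concentrations need antibody_mw (g/mol)")
            df.loc[ngml, "concentration"] = (
                df.loc[ngml, "concentration"].astype(float) / antibody_mw)
    rows = []
    for (model_id, drug), grp in df.groupby(["model_id", "drug"], sort=True):
        if "inhibition" in grp.columns and grp["inhibition"].notna().any():
            wells = grp[grp["concentration"].notna()]
            inhib = wells["inhibition"].astype(float)
        else:
            ctrl = grp[grp["concentration"].isna()]
            max_ctrl = ctrl.loc[ctrl["well_type"] == "max_ctrl", "reading"].mean()
            min_ctrl = ctrl.loc[ctrl["well_type"] == "min_ctrl", "reading"].mean()
            wells = grp[grp["concentration"].notna()]
            inhib = wells["reading"].astype(float).map(
                lambda r: percent_inhibition(r, max_ctrl, min_ctrl))
        pivot = pd.DataFrame({
            "concentration": wells["concentration"].astype(float),
            "replicate": wells["replicate"],
            "inhibition": inhib,
        }).pivot_table(index="concentration", columns="replicate",
                       values="inhibition")
        curve = DoseResponseCurve(
            drug=drug, model_id=model_id,
            concentrations=pivot.index.to_numpy(),
            inhibition=pivot.to_numpy(),
        )
        fit = fit_four_parameter_logistic(curve)
        rows.append({
            "model_id": model_id, "drug": drug, "ic50_uM": fit.ic50,
            "emax_pct": fit.emax, "hill": fit.hill,
            "category": categorize_pdo(fit).name, "censored": fit.ic50_censored,
            "converged": fit.converged,
        })
    return pd.DataFrame(rows)


def drug_correlation_matrix(
    sensitivities: pd.DataFrame, min_shared: int = 3
) -> pd.DataFrame:
    """Spearman drug x drug correlation of sensitivity profiles.

    ``sensitivities`` is a models x drugs table of log10 IC50 (PDO) or
    T/C (PDX).  Pairs sharing fewer than ``min_shared`` models are left
    as NaN (flagged missing).  The diagonal is exactly 1.
    """
    corr = sensitivities.corr(method="spearman", min_periods=min_shared)
    np.fill_diagonal(corr.values, 1.0)
    return corr
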