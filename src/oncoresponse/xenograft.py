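"""Xenograft (PDX) in-vivo drug sensitivity.

Tumour volumes from calliper length/width, endpoint treated/control
ratios (T/C) with the four-category growth-delay scale, relative tumour
volume (RTV) with RECIST-adapted CR/PR/SD/PD calls, responder
binarization for classifier training, and PDO/PDX sibling concordance.

Volumes use the standard ellipsoid approximation V = length * width^2 / 2
(mm^3).  Endpoint T/C is 100 * mean treated volume / mean control volume
at the last study day present in both arms (within a +/-2 day alignment
tolerance).  T/C <= 25% marks a responder (partial regression or stable
disease); RECIST calls derive from RTV: CR at 0, PR below 0.7, SD in
[0.7, 1.2], PD above 1.2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_response import ResponseCategory

__all__ = [
    "TumorMeasurement",
    "GrowthSeries",
    "PdxResponse",
    "tumor_volume",
    "endpoint_tc",
    "categorize_tc",
    "rtv_recist",
    "binarize_response",
    "sibling_concordance",
    "score_pdx",
    "score_growth_table",
]

TC_BOUNDS = (10.0, 25.0, 50.0)  # strong <=10, moderate (10,25], minor (25,50]


class DataError(ValueError):
    pass


def tumor_volume(length: float, width: float) -> float:
    """Ellipsoid tumour volume V = length * width^2 / 2 (mm^3)."""
    if length < 0 or width < 0:
        raise DataError("calliper measurements must be non-negative")
    return length * width * width / 2.0


@dataclass
class TumorMeasurement:
    """One calliper measurement; length/width swap-normalized on ingest."""

    day: float
    length: float
    width: float

    def __post_init__(self) -> None:
        if self.day < 0:
            raise DataError("study day must be >= 0")
        if self.length < 0 or self.width < 0:
            raise DataError("calliper measurements must be non-negative")
        if self.width > self.length:
            self.length, self.width = self.width, self.length

    @property
    def volume(self) -> float:
        return tumor_volume(self.length, self.width)


@dataclass
class GrowthSeries:
    """Per-animal tumour growth trajectory."""

    animal_id: str
    arm: str  # treated | control
    drug: str
    measurements: list[TumorMeasurement]

    def __post_init__(self) -> None:
        if self.arm not in ("treated", "control"):
            raise DataError(f"unknown arm {self.arm!r}")
        if len(self.measurements) < 2:
            raise DataError("need >=2 measurements per animal")
        days = [m.day for m in self.measurements]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise DataError("measurement days must be strictly increasing")

    @property
    def days(self) -> np.ndarray:
        return np.array([m.day for m in self.measurements])

    @property
    def volumes(self) -> np.ndarray:
        return np.array([m.volume for m in self.measurements])

    def volume_at(self, day: float, tol: float = 2.0) -> float | None:
        """Volume at the measurement nearest ``day`` within ``tol`` days."""
        deltas = np.abs(self.days - day)
        i = int(np.argmin(deltas))
        if deltas[i] <= tol:
            return float(self.measurements[i].volume)
        return None


@dataclass
class PdxResponse:
    """Derived per-(model, drug) in-vivo response summary."""

    model_id: str
    drug: str
    tc_percent: float
    tc_category: ResponseCategory
    rtv: float
    recist: str
    responder: bool


def _endpoint_day(treated: list[GrowthSeries], control: list[GrowthSeries],
                  tol: float = 2.0) -> tuple[float, float]:
    """Latest day present in both arms, nearest match within ``tol``."""
    t_days = sorted({float(m.day) for s in treated for m in s.measurements},
                    reverse=True)
    c_days = np.array(sorted({float(m.day) for s in control
                              for m in s.measurements}))
    for dt in t_days:
        deltas = np.abs(c_days - dt)
        i = int(np.argmin(deltas))
        if deltas[i] <= tol:
            return dt, float(c_days[i])
    raise DataError("no common endpoint day between arms (tolerance 2 days)")


def endpoint_tc(treated: list[GrowthSeries], control: list[GrowthSeries]) -> float:
    """Endpoint T/C in percent: 100 * mean treated / mean control volume.

    Animals are summarized by the arithmetic mean at the endpoint day.
    """
    if not treated or not control:
        raise DataError("both arms must be nonempty")
    day_t, day_c = _endpoint_day(treated, control)
    t_vols = [v for s in treated if (v := s.volume_at(day_t)) is not None]
    c_vols = [v for s in control if (v := s.volume_at(day_c)) is not None]
    if not t_vols or not c_vols:
        raise DataError("no animal measured at the endpoint day")
    c_mean = float(np.mean(c_vols))
    if c_mean == 0:
        raise DataError("control arm mean volume is zero at endpoint")
    return 100.0 * float(np.mean(t_vols)) / c_mean


def categorize_tc(tc_percent: float) -> ResponseCategory:
    """Four-category growth-delay call from endpoint T/C (%)."""
    if tc_percent < 0:
        raise DataError("T/C must be >= 0")
    if tc_percent <= TC_BOUNDS[0]:
        return ResponseCategory.STRONG
    if tc_percent <= TC_BOUNDS[1]:
        return ResponseCategory.MODERATE
    if tc_percent <= TC_BOUNDS[2]:
        return ResponseCategory.MINOR
    return ResponseCategory.RESISTANT


def rtv_recist(start_volume: float, end_volume: float) -> tuple[float, str]:
    """Relative tumour volume (end/start) and its RECIST-adapted call."""
    if start_volume <= 0:
        raise DataError("start volume must be positive")
    if end_volume < 0:
        raise DataError("end volume must be >= 0")
    rtv = end_volume / start_volume
    if rtv == 0:
        recist = "CR"
    elif rtv < 0.7:
        recist = "PR"
    elif rtv <= 1.2:
        recist = "SD"
    else:
        recist = "PD"
    return rtv, recist


def binarize_response(tc_category: ResponseCategory) -> bool:
    """Responder iff strong or moderate growth delay (T/C <= 25%)."""
    return tc_category in (ResponseCategory.STRONG, ResponseCategory.MODERATE)


def sibling_concordance(pdo_cat: ResponseCategory, pdx_cat: ResponseCategory) -> str:
    """Concordant if PDO and PDX categories differ by at most one rank."""
    return "concordant" if pdo_cat.rank_distance(pdx_cat) <= 1 else "discordant"


def score_pdx(model_id: str, drug: str, treated: list[GrowthSeries],
              control: list[GrowthSeries]) -> PdxResponse:
    """Full per-model response summary from both study arms.

    Arm-level RTV is the mean of per-animal RTVs over the treated arm;
    CR requires every treated animal to end at zero volume.
    """
    tc = endpoint_tc(treated, control)
    cat = categorize_tc(tc)
    rtvs, ends = [], []
    for s in treated:
        start = s.volumes[0]
        end = s.volumes[-1]
        if start <= 0:
            raise DataError(f"animal {s.animal_id}: start volume must be positive")
        rtvs.append(end / start)
        ends.append(end)
    arm_rtv = float(np.mean(rtvs))
    # arm_rtv == 0 iff every treated animal ended at zero volume, so the
    # arm-level CR rule coincides with rtv_recist on the mean RTV
    recist = rtv_recist(1.0, arm_rtv)[1]
    return PdxResponse(
        model_id=model_id, drug=drug, tc_percent=tc, tc_category=cat,
        rtv=arm_rtv, recist=recist, responder=binarize_response(cat),
    )


def score_growth_table(table: pd.DataFrame) -> pd.DataFrame:
    """Score a long-format growth table into per-(model, drug) responses.

    Expected columns: model_id, drug, animal_id, arm, day, length_mm,
    width_mm.  Returns one row per (model_id, drug) with T/C, category,
    RTV, RECIST and the responder flag.
    """
    required = {"model_id", "drug", "animal_id", "arm", "day",
                "length_mm", "width_mm"}
    missing = required - set(table.columns)
    if missing:
        raise DataError(f"growth table missing columns: {sorted(missing)}")
    rows = []
    for (model_id, drug), grp in table.groupby(["model_id", "drug"], sort=True):
        arms: dict[str, list[GrowthSeries]] = {"treated": [], "control": []}
        for (animal, arm), sub in grp.groupby(["animal_id", "arm"], sort=True):
            sub = sub.sort_values("day")
            meas = [TumorMeasurement(day=r.day, length=r.length_mm, width=r.width_mm)
                    for r in sub.itertuples()]
            arms[arm].append(GrowthSeries(str(animal), arm, drug, meas))
        resp = score_pdx(model_id, drug, arms["treated"], arms["control"])
        rows.append({
            "model_id": model_id, "drug": drug,
            "tc_percent": resp.tc_percent, "tc_category": resp.tc_category.name,
            "rtv": resp.rtv, "recist": resp.recist, "responder": resp.responder,
        })
    return pd.DataFrame(rows)
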