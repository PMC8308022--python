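"""Clinical scoring for the biofeedback workflow.

Covers the Facial Disability Index (FDI) — two five-item subscales
(physical function, social function/wellbeing), each 0-100, combined as
the mean of the two parts divided by 100 — plus quantification of the
biofeedback effect: percent change of per-muscle activation maxima between
the without- and with-biofeedback conditions, with a 20% clinical-relevance
threshold, and Cohen's d (pooled-SD form) for group summaries.

A bundled five-case clinical reference dataset (FDI subscales and
per-gesture EMG activation maxima on the x1000 integer scale for five
patients with facial palsy) ships with the package for worked examples and
regression tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

from .emg import GESTURES, MUSCLES, EmgSummary
from .errors import ParameterError, SchemaMismatchError

__all__ = [
    "RELEVANCE_THRESHOLD_PCT", "FdiScore", "ChangeRecord", "EffectSize",
    "fdi_total", "fdi_from_items", "percent_change", "cohens_d", "case_report",
    "load_fdi_cases", "load_emg_maxima_cases", "case_change_records",
]

#: minimum |percent change| regarded as clinically relevant
RELEVANCE_THRESHOLD_PCT = 20.0


def _round_half_up(value: float, decimals: int = 0) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FdiScore:
    """FDI subscales (0-100 each) and total (0-1).

    ``total`` is exactly ``((physical + social) / 2) / 100``; lower scores
    indicate greater disability.  ``total_2dp`` is the 2-decimal
    presentation value.
    """

    physical: float
    social: float

    def __post_init__(self) -> None:
        for v in (self.physical, self.social):
            if not 0.0 <= v <= 100.0:
                raise ParameterError(f"subscale {v} outside [0, 100]")

    @property
    def total(self) -> float:
        return ((self.physical + self.social) / 2.0) / 100.0

    @property
    def total_2dp(self) -> float:
        return _round_half_up(self.total, 2)


def fdi_total(physical: float, social: float) -> FdiScore:
    """Combine the two FDI subscales into the 0-1 total."""
    return FdiScore(physical=float(physical), social=float(social))


def fdi_from_items(
    item_responses,
    response_min: float = 1.0,
    response_max: float = 6.0,
    missing: str = "error",
) -> float:
    """Linear 0-100 transform of a five-item FDI subscale.

    All-minimum responses map to 0, all-maximum to 100; the transform is
    linear in the item sum.  ``missing`` controls None/NaN handling:
    ``"error"`` raises, ``"exclude-and-rescale"`` scores the mean of the
    available items.
    """
    if response_max <= response_min:
        raise ParameterError("response_max must exceed response_min")
    vals = [None if (r is None or (isinstance(r, float) and math.isnan(r))) else float(r)
            for r in item_responses]
    if len(vals) != 5:
        raise ParameterError("a subscale has exactly 5 items")
    present = [v for v in vals if v is not None]
    if len(present) < len(vals):
        if missing == "error":
            raise ParameterError("missing item response")
        if missing != "exclude-and-rescale":
            raise ParameterError(f"unknown missing policy {missing!r}")
        if not present:
            raise ParameterError("all item responses missing")
    for v in present:
        if not response_min <= v <= response_max:
            raise ParameterError(f"response {v} outside scale")
    mean = float(np.mean(present))
    return 100.0 * (mean - response_min) / (response_max - response_min)


@dataclass(frozen=True)
class ChangeRecord:
    """Percent change of an activation maximum between conditions.

    Signed change = (with - without) / without x 100; a negative signed
    change is reported as a positive ``reduction_pct``.  ``relevant`` is
    true when |change| meets the 20% threshold.  When the without value is
    zero the change is undefined and flagged rather than computed; when
    either value is missing the record is flagged missing.
    """

    gesture: str
    muscle: str
    without_value: float | None
    with_value: float | None
    percent_change: float | None
    undefined: bool = False
    missing: bool = False

    @property
    def relevant(self) -> bool:
        return (
            self.percent_change is not None
            and abs(self.percent_change) >= RELEVANCE_THRESHOLD_PCT
        )

    @property
    def reduction_pct(self) -> float | None:
        if self.percent_change is None or self.percent_change >= 0:
            return None
        return -self.percent_change

    @property
    def presented_pct(self) -> int | None:
        """Integer percent for tables, round-half-up on the magnitude."""
        if self.percent_change is None:
            return None
        mag = _round_half_up(abs(self.percent_change), 0)
        return int(math.copysign(mag, self.percent_change))


def percent_change(
    without_value: float, with_value: float, gesture: str = "", muscle: str = ""
) -> ChangeRecord:
    """Percent change of ``with`` relative to ``without`` (the baseline)."""
    w, v = float(without_value), float(with_value)
    if w < 0 or v < 0:
        raise ParameterError("activation maxima must be >= 0")
    if w == 0:
        return ChangeRecord(gesture, muscle, w, v, None, undefined=True)
    pct = (v - w) / w * 100.0
    return ChangeRecord(gesture, muscle, w, v, pct)


@dataclass(frozen=True)
class EffectSize:
    """Cohen's d with the (n-1)-weighted pooled standard deviation."""

    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    d: float
    infinite: bool = False


def cohens_d(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> EffectSize:
    """d = (mean_a - mean_b) / pooled SD; sign follows mean_a - mean_b."""
    if n_a < 2 or n_b < 2:
        raise ParameterError("need n >= 2 per group")
    if sd_a < 0 or sd_b < 0:
        raise ParameterError("standard deviations must be >= 0")
    pooled_var = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
    diff = mean_a - mean_b
    if pooled_var == 0:
        if diff == 0:
            d, infinite = 0.0, False
        else:
            d, infinite = math.copysign(math.inf, diff), True
    else:
        d, infinite = diff / math.sqrt(pooled_var), False
    return EffectSize(mean_a, mean_b, sd_a, sd_b, n_a, n_b, d, infinite)


# ---------------------------------------------------------------------------
# case report: gesture x muscle x condition grid plus change records
# ---------------------------------------------------------------------------

def case_report(
    summary_without: EmgSummary,
    summary_with: EmgSummary,
    fdi: FdiScore | None = None,
    scale_x1000: bool = True,
) -> tuple[pd.DataFrame, list[ChangeRecord]]:
    """Build the per-case results grid and its change records.

    The grid has one row per gesture and, per muscle, ``without``/``with``
    columns (missing cells rendered as "-"), matching the layout of
    clinical maxima tables; change records carry the relevance flags.
    """
    keys_w = set(summary_without.values_mV)
    keys_v = set(summary_with.values_mV)
    if keys_w != keys_v:
        raise SchemaMismatchError("with/without summaries cover different keys")
    factor = 1000.0 if scale_x1000 else 1.0

    records: list[ChangeRecord] = []
    rows = []
    for gesture in GESTURES:
        row: dict[str, object] = {"gesture": gesture}
        for muscle in MUSCLES:
            key = (gesture, muscle)
            wo = summary_without.values_mV.get(key)
            wi = summary_with.values_mV.get(key)
            wo_s = None if wo is None or np.isnan(wo) else wo * factor
            wi_s = None if wi is None or np.isnan(wi) else wi * factor
            row[f"{muscle}_without"] = "-" if wo_s is None else wo_s
            row[f"{muscle}_with"] = "-" if wi_s is None else wi_s
            if wo_s is None or wi_s is None:
                records.append(
                    ChangeRecord(gesture, muscle, wo_s, wi_s, None, missing=True)
                )
            else:
                records.append(percent_change(wo_s, wi_s, gesture, muscle))
        rows.append(row)
    grid = pd.DataFrame(rows)
    if fdi is not None:
        grid.attrs["fdi_total"] = fdi.total
    return grid, records


# ---------------------------------------------------------------------------
# bundled five-case reference dataset
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("mirrorface.data").joinpath(name)


def load_fdi_cases() -> pd.DataFrame:
    """FDI subscales for the five reference cases (case, physical, social)."""
    with resources.as_file(_data_path("fdi_cases.csv")) as p:
        return pd.read_csv(p)


def load_emg_maxima_cases() -> pd.DataFrame:
    """Per-gesture, per-muscle activation maxima (x1000 scale) for the five
    reference cases, without/with biofeedback; blank cells are missing data."""
    with resources.as_file(_data_path("emg_maxima_cases.csv")) as p:
        return pd.read_csv(p)


def case_change_records(case: int) -> list[ChangeRecord]:
    """Change records for one reference case, computed from the bundled
    maxima table (missing cells excluded, zero baselines flagged)."""
    df = load_emg_maxima_cases()
    sub = df[df["case"] == case]
    if sub.empty:
        raise ParameterError(f"unknown case {case}")
    records = []
    for _, row in sub.iterrows():
        wo, wi = row["without"], row["with"]
        if pd.isna(wo) or pd.isna(wi):
            records.append(
                ChangeRecord(row["gesture"], row["muscle"], None, None, None,
                             missing=True)
            )
        else:
            records.append(
                percent_change(float(wo), float(wi), row["gesture"], row["muscle"])
            )
    return records
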