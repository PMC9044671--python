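"""Boll-pixel-ratio yield estimation: regression fit, prediction, reporting.

The yield model is a simple linear calibration between the cotton boll
pixel ratio x of a sample plot's image (in PERCENT of pixels) and the
hand-harvested seed-cotton weight y of that plot (grams per plot, default
plot 2.3 m^2):

    y = a * x + b

The published field calibration is a = 38.6, b = 34 with R^2 = 0.91 over
20 equidistant sample plots.  Field-level estimation follows five-point
sampling: the field's boll ratio is the mean over its five sample images,
pushed through the regression and converted to kg/ha.

Mask-level ratios everywhere else in this package are fractions in [0, 1];
this module's regression-facing API takes percent.  The conversion happens
exactly once, inside :func:`estimate_field`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import r_squared

__all__ = [
    "YieldRegression",
    "FieldEstimate",
    "boll_pixel_ratio",
    "fit_regression",
    "predict_sample_yield",
    "to_kg_per_ha",
    "from_kg_per_ha",
    "estimate_field",
    "error_report",
    "round_half_up",
]

DEFAULT_SAMPLE_AREA_M2 = 2.3  # 230 cm x 100 cm sampling plot


@dataclass(frozen=True)
class YieldRegression:
    """Linear ratio-to-yield calibration for one sample-plot geometry."""

    slope: float  # g per (plot * percent ratio)
    intercept: float  # g per plot
    r2: float
    sample_area_m2: float = DEFAULT_SAMPLE_AREA_M2

    def __post_init__(self) -> None:
        if self.sample_area_m2 <= 0:
            raise ValueError("sample_area_m2 must be > 0")


@dataclass(frozen=True)
class FieldEstimate:
    field_id: str
    mean_ratio_percent: float
    estimated_yield_kg_ha: float
    measured_yield_kg_ha: float | None = None

    @property
    def relative_error_percent(self) -> float | None:
        if self.measured_yield_kg_ha is None:
            return None
        return relative_error(self.measured_yield_kg_ha, self.estimated_yield_kg_ha)


def boll_pixel_ratio(mask: np.ndarray) -> float:
    """Foreground-pixel count over total pixels, as an exact fraction."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("mask is empty")
    bad = np.setdiff1d(np.unique(mask), [0, 1])
    if bad.size:
        raise ValueError(f"mask is not binary; offending values: {bad.tolist()}")
    return float(int(mask.sum()) / mask.size)


def fit_regression(
    ratios_percent: Sequence[float],
    yields_g: Sequence[float],
    sample_area_m2: float = DEFAULT_SAMPLE_AREA_M2,
) -> YieldRegression:
    """Ordinary least squares of plot yield on boll pixel ratio (percent).

    The reported fit R^2 applies the coefficient-of-determination form used
    for segmentation accuracy to the (observed, fitted) yield pairs; because
    an OLS fit with intercept makes the fitted mean equal the observed mean,
    this equals the conventional R^2 of the regression.
    """
    x = np.asarray(ratios_percent, dtype=float)
    y = np.asarray(yields_g, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need >= 2 equal-length (ratio, yield) pairs")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all ratios identical")
    res = stats.linregress(x, y)
    fitted = res.slope * x + res.intercept
    return YieldRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=r_squared(y, fitted).r2,
        sample_area_m2=sample_area_m2,
    )


def predict_sample_yield(reg: YieldRegression, ratio_percent: float) -> float:
    """Predicted grams per sample plot at a boll pixel ratio in percent."""
    if ratio_percent < 0:
        raise ValueError("ratio_percent must be >= 0")
    return reg.slope * ratio_percent + reg.intercept


def to_kg_per_ha(yield_g: float, sample_area_m2: float = DEFAULT_SAMPLE_AREA_M2) -> float:
    """Convert grams per sample plot to kg per hectare."""
    if sample_area_m2 <= 0:
        raise ValueError("sample_area_m2 must be > 0")
    return yield_g / 1000.0 * 10000.0 / sample_area_m2


def from_kg_per_ha(yield_kg_ha: float, sample_area_m2: float = DEFAULT_SAMPLE_AREA_M2) -> float:
    """Inverse of :func:`to_kg_per_ha`."""
    if sample_area_m2 <= 0:
        raise ValueError("sample_area_m2 must be > 0")
    return yield_kg_ha * 1000.0 * sample_area_m2 / 10000.0


def relative_error(measured: float, estimated: float) -> float:
    """100 * |estimated - measured| / measured."""
    if measured <= 0:
        raise ValueError("measured yield must be > 0")
    return 100.0 * abs(estimated - measured) / measured


def estimate_field(
    reg: YieldRegression,
    sample_masks: Sequence[np.ndarray],
    field_id: str = "field",
    measured_yield_kg_ha: float | None = None,
) -> FieldEstimate:
    """Five-point field estimate: mean ratio -> regression -> kg/ha.

    Accepts any number >= 1 of sample masks (the field convention is five);
    the estimate is invariant to their order.
    """
    if len(sample_masks) == 0:
        raise ValueError("need at least one sample mask")
    mean_ratio_pct = 100.0 * float(np.mean([boll_pixel_ratio(m) for m in sample_masks]))
    grams = predict_sample_yield(reg, mean_ratio_pct)
    if grams < 0:
        warnings.warn("regression predicts negative yield; clamping to 0", stacklevel=2)
        grams = 0.0
    return FieldEstimate(
        field_id=field_id,
        mean_ratio_percent=mean_ratio_pct,
        estimated_yield_kg_ha=to_kg_per_ha(grams, reg.sample_area_m2),
        measured_yield_kg_ha=measured_yield_kg_ha,
    )


def round_half_up(value: float, decimals: int) -> float:
    """Decimal round-half-up (school rounding, unlike numpy's half-even)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _report_decimals(err: float) -> int:
    # sub-1% errors are printed with 2 decimals, larger ones with 1
    return 2 if err < 1.0 else 1


def error_report(fields: Sequence[tuple]) -> pd.DataFrame:
    """Per-field relative yield errors plus their unweighted average.

    ``fields``: (field_id, measured_kg_ha, estimated_kg_ha) triples.
    Returns one row per field with raw and rounded relative error and a
    final ``average`` row; the average is the mean of the raw per-field
    errors, rounded to 1 decimal.
    """
    if len(fields) == 0:
        raise ValueError("no fields given")
    rows = []
    raws = []
    for field_id, measured, estimated in fields:
        err = relative_error(measured, estimated)
        raws.append(err)
        rows.append(
            {
                "field_id": str(field_id),
                "measured_kg_ha": measured,
                "estimated_kg_ha": estimated,
                "difference_kg_ha": round_half_up(abs(estimated - measured), 1),
                "relative_error_raw": err,
                "relative_error_percent": round_half_up(err, _report_decimals(err)),
            }
        )
    avg = float(np.mean(raws))
    rows.append(
        {
            "field_id": "average",
            "measured_kg_ha": np.nan,
            "estimated_kg_ha": np.nan,
            "difference_kg_ha": np.nan,
            "relative_error_raw": avg,
            "relative_error_percent": round_half_up(avg, 1),
        }
    )
    return pd.DataFrame(rows)
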