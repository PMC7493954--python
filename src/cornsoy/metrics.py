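"""Categorical-map validation statistics.

Implements the evaluation suite for crop-type maps: pixel-level confusion
and overall/user's/producer's accuracy against a reference map, per-region
area aggregation, the raw-value coefficient of determination

    R^2 = 1 - sum_i (y_i - yhat_i)^2 / sum_i (y_i - ybar)^2

computed on areas directly (no refitted regression; can be negative),
the squared Pearson correlation r^2 as a separate statistic, soybean-corn
rotation fractions between consecutive years, and linear area trends.

Undefined statistics (zero denominators) propagate as None, never as 0 or
silent NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from cornsoy.classify import CropMap
from cornsoy.synth import CORN, CROP_CLASSES, LabelRaster, RegionPartition, SOYBEAN

__all__ = [
    "ACRE_M2",
    "AREA_UNITS",
    "ConfusionMatrix",
    "RotationRecord",
    "confusion",
    "overall_accuracy",
    "users_producers",
    "aggregate_area",
    "r_squared",
    "squared_correlation",
    "rotation_fraction",
    "area_trend",
    "build_area_table",
]

ACRE_M2 = 4046.8564224
AREA_UNITS: Mapping[str, float] = {"m2": 1.0, "ha": 1e4, "acre": ACRE_M2}


@dataclass
class ConfusionMatrix:
    """3x3 counts over crop classes; rows = reference, columns = prediction."""

    counts: np.ndarray
    classes: Tuple[int, ...] = CROP_CLASSES
    excluded: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    def _idx(self, c: int) -> int:
        try:
            return self.classes.index(c)
        except ValueError:
            raise ValueError(
                f"unknown class {c}; expected one of {self.classes}"
            ) from None

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def tp(self, c: int) -> int:
        i = self._idx(c)
        return int(self.counts[i, i])

    def fp(self, c: int) -> int:
        i = self._idx(c)
        return int(self.counts[:, i].sum() - self.counts[i, i])

    def fn(self, c: int) -> int:
        i = self._idx(c)
        return int(self.counts[i, :].sum() - self.counts[i, i])

    def count(self, ref: int, pred: int) -> int:
        return int(self.counts[self._idx(ref), self._idx(pred)])


def _as_data(m) -> np.ndarray:
    if isinstance(m, CropMap):
        return m.data
    if isinstance(m, LabelRaster):
        return m.data
    return np.asarray(m)


def confusion(pred, ref) -> ConfusionMatrix:
    """Count (reference class, predicted class) pairs over comparable pixels.

    Only pixels where *both* maps hold a crop code in {1, 5, 9} are
    compared; pixels unclassified (0) or non-crop (255) in either map are
    excluded symmetrically and counted in ``excluded``.
    """
    p = _as_data(pred)
    r = _as_data(ref)
    if p.shape != r.shape:
        raise ValueError(f"geometry mismatch: pred {p.shape} vs ref {r.shape}")
    crop = np.array(CROP_CLASSES)
    ok = np.isin(p, crop) & np.isin(r, crop)
    excluded = int(ok.size - ok.sum())
    idx = {c: i for i, c in enumerate(CROP_CLASSES)}
    k = len(CROP_CLASSES)
    lut = np.zeros(256, dtype=np.int64)
    for c, i in idx.items():
        lut[c] = i
    flat = lut[r[ok].astype(np.int64)] * k + lut[p[ok].astype(np.int64)]
    counts = np.bincount(flat, minlength=k * k).reshape(k, k)
    return ConfusionMatrix(counts=counts, excluded=excluded)


def overall_accuracy(cm: ConfusionMatrix) -> Optional[float]:
    """Fraction of compared pixels with the same label; None if nothing compared."""
    if cm.total == 0:
        return None
    return float(np.trace(cm.counts) / cm.total)


def users_producers(
    cm: ConfusionMatrix, c: int
) -> Tuple[Optional[float], Optional[float]]:
    """(user's accuracy, producer's accuracy) = (precision, recall) for class c.

    user's = TP / (TP + FP); producer's = TP / (TP + FN). A zero denominator
    yields None for that component.
    """
    tp, fp, fn = cm.tp(c), cm.fp(c), cm.fn(c)
    ua = tp / (tp + fp) if (tp + fp) > 0 else None
    pa = tp / (tp + fn) if (tp + fn) > 0 else None
    return ua, pa


def aggregate_area(
    crop_map, partition: RegionPartition, class_code: int, unit: str = "m2"
) -> Dict[int, float]:
    """Per-region area of one class: pixel count x pixel area, unit-converted."""
    if unit not in AREA_UNITS:
        raise ValueError(f"unknown area unit {unit!r}; expected one of {sorted(AREA_UNITS)}")
    data = _as_data(crop_map)
    if data.shape != partition.shape:
        raise ValueError(
            f"geometry mismatch: map {data.shape} vs partition {partition.shape}"
        )
    pixel_area = crop_map.pixel_area
    factor = pixel_area / AREA_UNITS[unit]
    return {
        int(region): float((data[partition.mask(region)] == class_code).sum() * factor)
        for region in partition.regions
    }


def r_squared(y: Sequence[float], yhat: Sequence[float]) -> Optional[float]:
    """Raw-value coefficient of determination, in (-inf, 1].

    Computed on the values themselves, not a refitted regression, so it
    penalizes bias as well as scatter. None when y is constant.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have the same length")
    if y.size < 2:
        raise ValueError("need at least 2 values")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return None
    ss_res = float(((y - yhat) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def squared_correlation(y: Sequence[float], yhat: Sequence[float]) -> Optional[float]:
    """Squared Pearson correlation r^2 — a different statistic from the
    raw-value R^2 above (insensitive to bias and scale). None if either
    series is constant."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have the same length")
    if y.std() == 0.0 or yhat.std() == 0.0:
        return None
    return float(np.corrcoef(y, yhat)[0, 1] ** 2)


@dataclass
class RotationRecord:
    """Soybean-corn rotation summary for one region and year pair."""

    region: int
    year_prev: int
    year_curr: int
    soy_to_corn_area: float
    corn_to_corn_area: float
    fraction: Optional[float]  # None when no corn followed corn or soy


def rotation_fraction(
    map_prev, map_curr, partition: RegionPartition, unit: str = "m2"
) -> List[RotationRecord]:
    """Per-region fraction of current corn area previously under soybean.

    fraction = soy->corn / (soy->corn + corn->corn); current-year corn whose
    prior class is anything else is excluded from numerator and denominator.
    """
    prev = _as_data(map_prev)
    curr = _as_data(map_curr)
    if prev.shape != curr.shape or prev.shape != partition.shape:
        raise ValueError("rotation inputs must share geometry")
    factor = map_curr.pixel_area / AREA_UNITS[unit] if isinstance(map_curr, CropMap) else 1.0
    year_prev = map_prev.year if isinstance(map_prev, CropMap) else -1
    year_curr = map_curr.year if isinstance(map_curr, CropMap) else -1
    out: List[RotationRecord] = []
    for region in partition.regions:
        sel = partition.mask(region) & (curr == CORN)
        s2c = float((prev[sel] == SOYBEAN).sum()) * factor
        c2c = float((prev[sel] == CORN).sum()) * factor
        denom = s2c + c2c
        out.append(
            RotationRecord(
                region=int(region),
                year_prev=year_prev,
                year_curr=year_curr,
                soy_to_corn_area=s2c,
                corn_to_corn_area=c2c,
                fraction=(s2c / denom) if denom > 0 else None,
            )
        )
    return out


def area_trend(years: Sequence[float], areas: Sequence[float]) -> Optional[float]:
    """OLS slope of area on calendar year; None with < 2 distinct years."""
    years = np.asarray(years, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if years.shape != areas.shape:
        raise ValueError("years and areas must have the same length")
    if np.unique(years).size < 2:
        return None
    return float(np.polyfit(years, areas, 1)[0])


def build_area_table(
    maps: Mapping[int, CropMap],
    references: Mapping[int, LabelRaster],
    partition: RegionPartition,
    unit: str = "ha",
) -> pd.DataFrame:
    """Predicted vs reference per-region, per-year, per-class area table."""
    rows = []
    for year in sorted(maps):
        cmap = maps[year]
        ref = references[year]
        ref_wrapped = CropMap(data=ref.data, year=year, pixel_area=ref.pixel_area)
        for cls in CROP_CLASSES:
            pred_area = aggregate_area(cmap, partition, cls, unit)
            ref_area = aggregate_area(ref_wrapped, partition, cls, unit)
            for region in partition.regions:
                rows.append(
                    {
                        "region": int(region),
                        "year": int(year),
                        "class_code": int(cls),
                        "predicted_area": pred_area[region],
                        "reference_area": ref_area[region],
                        "unit": unit,
                    }
                )
    return pd.DataFrame(rows)
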