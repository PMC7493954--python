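"""Per-region random-forest crop classification and cropland masking.

One random forest (500 trees, otherwise library defaults) is trained per
region on the 20 harmonic features and three crop classes, then applied to
every pixel of the region. Pixels with insufficient observations receive
code 0 (unclassified); a cropland mask — keyed by the last available mask
year — overrides non-cropland pixels to 255.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from cornsoy.features import HarmonicBasisSpec, feature_names
from cornsoy.rng import substream
from cornsoy.synth import (
    CROP_CLASSES,
    NONCROP,
    RegionPartition,
    UNCLASSIFIED,
)

__all__ = [
    "CropMap",
    "ClassifierModel",
    "train",
    "predict_map",
    "predict_by_region",
    "mask_year_for",
    "apply_mask",
]

LEGAL_MAP_CODES = (UNCLASSIFIED,) + CROP_CLASSES + (NONCROP,)


@dataclass
class CropMap:
    """Single-year categorical map: {0 unclassified, 1 corn, 5 soy, 9 other, 255 non-crop}."""

    data: np.ndarray
    year: int
    pixel_area: float
    region: Optional[int] = None

    def __post_init__(self) -> None:
        bad = np.setdiff1d(np.unique(self.data), np.array(LEGAL_MAP_CODES))
        if bad.size:
            raise ValueError(f"illegal map codes {bad.tolist()}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.data.shape


@dataclass
class ClassifierModel:
    """Trained ensemble plus the metadata needed to apply it safely."""

    estimator: RandomForestClassifier
    region: int
    n_trees: int
    seed: int
    feature_names: Tuple[str, ...]
    classes: Tuple[int, ...]


def train(
    sample: pd.DataFrame,
    region: int,
    n_trees: int = 500,
    seed: int = 0,
    spec: HarmonicBasisSpec = HarmonicBasisSpec(),
) -> ClassifierModel:
    """Fit a random forest on the training records of one region.

    Requires every crop class to be present (a forest cannot learn an
    absent class); ties among tree votes resolve to the lowest class code.
    Deterministic given data and seed.
    """
    cols = [f"f{i + 1}" for i in range(4 * spec.n_basis)]
    present = set(sample["label"].unique())
    missing = [c for c in CROP_CLASSES if c not in present]
    if missing:
        raise ValueError(
            f"region {region}: class(es) {missing} absent from training data"
        )
    rf_seed = int(substream(seed, "rf", region).integers(0, 2**31 - 1))
    est = RandomForestClassifier(
        n_estimators=n_trees, random_state=rf_seed, n_jobs=1
    )
    est.fit(sample[cols].to_numpy(), sample["label"].to_numpy())
    return ClassifierModel(
        estimator=est,
        region=region,
        n_trees=n_trees,
        seed=seed,
        feature_names=tuple(feature_names(spec)),
        classes=tuple(int(c) for c in est.classes_),
    )


def predict_map(
    model: ClassifierModel,
    features: np.ndarray,
    insufficient: np.ndarray,
    year: int,
    pixel_area: float,
    feature_order: Optional[Sequence[str]] = None,
    tile_rows: int = 64,
) -> CropMap:
    """Predict a pre-mask crop map: codes {1, 5, 9}, with 0 where insufficient.

    Prediction proceeds tile-by-tile over row blocks with bounded memory;
    tiling does not change results. ``feature_order``, when given, must
    match the ordering the model was trained with.
    """
    if feature_order is not None and tuple(feature_order) != model.feature_names:
        raise ValueError(
            "feature ordering mismatch: raster order "
            f"{tuple(feature_order)} != model order {model.feature_names}"
        )
    h, w, p = features.shape
    if len(model.feature_names) != p:
        raise ValueError(
            f"feature raster has {p} bands, model expects {len(model.feature_names)}"
        )
    out = np.full((h, w), UNCLASSIFIED, dtype=np.uint8)
    for r0 in range(0, h, tile_rows):
        r1 = min(r0 + tile_rows, h)
        ok = ~insufficient[r0:r1]
        if not ok.any():
            continue
        block = features[r0:r1][ok]
        pred = model.estimator.predict(block).astype(np.uint8)
        tile = out[r0:r1]
        tile[ok] = pred
        out[r0:r1] = tile
    return CropMap(data=out, year=year, pixel_area=pixel_area, region=model.region)


def predict_by_region(
    models: Mapping[int, ClassifierModel],
    features: np.ndarray,
    insufficient: np.ndarray,
    partition: RegionPartition,
    year: int,
    pixel_area: float,
) -> CropMap:
    """Stitch per-region model predictions into one scene-wide map."""
    h, w, _ = features.shape
    out = np.full((h, w), UNCLASSIFIED, dtype=np.uint8)
    for region in partition.regions:
        model = models.get(region)
        if model is None:
            raise ValueError(f"no model for region {region}")
        sel = partition.mask(region) & ~insufficient
        if sel.any():
            out[sel] = model.estimator.predict(features[sel]).astype(np.uint8)
    return CropMap(data=out, year=year, pixel_area=pixel_area)


def mask_year_for(target_year: int, available_mask_years: Sequence[int]) -> int:
    """Mask-year rule: latest available year <= target, else the earliest.

    E.g. with masks {2001, 2004, 2006, 2008, 2011, 2013, 2016}, target 2009
    uses 2008; targets before the first mask fall forward to the earliest
    one (2001).
    """
    years = sorted(available_mask_years)
    if not years:
        raise ValueError("available_mask_years is empty")
    eligible = [y for y in years if y <= target_year]
    return eligible[-1] if eligible else years[0]


def apply_mask(crop_map: CropMap, mask: np.ndarray) -> CropMap:
    """Override non-cropland pixels to 255; cropland pixels unchanged. Idempotent."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != crop_map.shape:
        raise ValueError(
            f"mask geometry {mask.shape} != map geometry {crop_map.shape}"
        )
    data = crop_map.data.copy()
    data[~mask] = NONCROP
    return CropMap(
        data=data,
        year=crop_map.year,
        pixel_area=crop_map.pixel_area,
        region=crop_map.region,
    )
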