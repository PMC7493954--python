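"""On-disk artifact formats: TIFF rasters with JSON/CSV sidecars.

Every intermediate product of the pipeline round-trips through plain files
so any stage can be resumed from disk: scene cubes as per-date multi-band
TIFFs plus a CSV manifest, categorical rasters and masks as single-band
TIFFs with a JSON sidecar carrying pixel geometry, feature rasters as a
multi-band TIFF with a band-naming sidecar, sample sets as CSV, models via
joblib, and reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import joblib
import numpy as np
import pandas as pd
import tifffile

from cornsoy.classify import ClassifierModel, CropMap
from cornsoy.synth import BANDS, LabelRaster, RegionPartition, SceneStack

__all__ = [
    "write_scene",
    "read_scene",
    "write_labels",
    "read_labels",
    "write_partition",
    "read_partition",
    "write_mask",
    "read_mask",
    "write_features",
    "read_features",
    "write_samples",
    "read_samples",
    "write_map",
    "read_map",
    "write_model",
    "read_model",
    "write_report",
    "read_report",
]


def _write_sidecar(path: Path, meta: dict) -> None:
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def _read_sidecar(path: Path) -> dict:
    return json.loads(path.with_suffix(".json").read_text())


# -- scene cubes ------------------------------------------------------------

def write_scene(directory: str | Path, stack: SceneStack) -> None:
    """Per-date multi-band TIFFs (6 reflectance bands + validity) + manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, t in enumerate(stack.times):
        arr = np.concatenate(
            [stack.values[i], stack.valid[i][None].astype(np.float32)], axis=0
        )
        tifffile.imwrite(d / f"obs_{i:03d}.tif", arr)
        rows.append(
            {"index": i, "t": float(t), "n_valid": int(stack.valid[i].sum())}
        )
    pd.DataFrame(rows).to_csv(d / "manifest.csv", index=False)
    (d / "bands.json").write_text(json.dumps(list(stack.bands)))


def read_scene(directory: str | Path) -> SceneStack:
    d = Path(directory)
    manifest = pd.read_csv(d / "manifest.csv")
    bands = tuple(json.loads((d / "bands.json").read_text()))
    values, valid = [], []
    for i in manifest["index"]:
        arr = tifffile.imread(d / f"obs_{int(i):03d}.tif")
        values.append(arr[: len(bands)])
        valid.append(arr[len(bands)] > 0.5)
    return SceneStack(
        times=manifest["t"].to_numpy(dtype=float),
        bands=bands,
        values=np.stack(values),
        valid=np.stack(valid),
    )


# -- categorical rasters ----------------------------------------------------

def write_labels(path: str | Path, labels: LabelRaster) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, labels.data)
    _write_sidecar(path, {"pixel_area": labels.pixel_area})


def read_labels(path: str | Path) -> LabelRaster:
    path = Path(path)
    return LabelRaster(
        data=tifffile.imread(path), pixel_area=_read_sidecar(path)["pixel_area"]
    )


def write_partition(path: str | Path, partition: RegionPartition) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, partition.region_ids.astype(np.int32))
    _write_sidecar(path, {"regions": list(partition.regions)})


def read_partition(path: str | Path) -> RegionPartition:
    path = Path(path)
    return RegionPartition(
        region_ids=tifffile.imread(path),
        regions=tuple(_read_sidecar(path)["regions"]),
    )


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, mask.astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)) > 0


# -- feature rasters --------------------------------------------------------

def write_features(
    path: str | Path,
    features: np.ndarray,
    insufficient: np.ndarray,
    band_names: Tuple[str, ...],
) -> None:
    """Multi-band TIFF (bands-first) + JSON sidecar naming each band;
    the insufficiency flag raster sits beside it as ``<stem>_flags.tif``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.moveaxis(features, -1, 0).astype(np.float64))
    tifffile.imwrite(
        path.with_name(path.stem + "_flags.tif"), insufficient.astype(np.uint8)
    )
    _write_sidecar(path, {"band_names": list(band_names)})


def read_features(path: str | Path) -> Tuple[np.ndarray, np.ndarray, Tuple[str, ...]]:
    path = Path(path)
    feats = np.moveaxis(tifffile.imread(path), 0, -1)
    flags = tifffile.imread(path.with_name(path.stem + "_flags.tif")) > 0
    names = tuple(_read_sidecar(path)["band_names"])
    return feats, flags, names


# -- samples, maps, models, reports ----------------------------------------

def write_samples(path: str | Path, sample: pd.DataFrame) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sample.to_csv(path, index=False)


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    df["split"] = df["split"].fillna("")
    return df


def write_map(path: str | Path, crop_map: CropMap) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, crop_map.data)
    _write_sidecar(
        path,
        {
            "year": crop_map.year,
            "pixel_area": crop_map.pixel_area,
            "region": crop_map.region,
        },
    )


def read_map(path: str | Path) -> CropMap:
    path = Path(path)
    meta = _read_sidecar(path)
    return CropMap(
        data=tifffile.imread(path),
        year=meta["year"],
        pixel_area=meta["pixel_area"],
        region=meta.get("region"),
    )


def write_model(path: str | Path, model: ClassifierModel) -> None:
    """Model as joblib plus a JSON metadata sidecar (the metadata, not the
    pickle, is what downstream stages check)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump(model.estimator, path)
    _write_sidecar(
        path,
        {
            "region": model.region,
            "n_trees": model.n_trees,
            "seed": model.seed,
            "feature_names": list(model.feature_names),
            "classes": list(model.classes),
        },
    )


def read_model(path: str | Path) -> ClassifierModel:
    path = Path(path)
    meta = _read_sidecar(path)
    return ClassifierModel(
        estimator=joblib.load(path),
        region=meta["region"],
        n_trees=meta["n_trees"],
        seed=meta["seed"],
        feature_names=tuple(meta["feature_names"]),
        classes=tuple(meta["classes"]),
    )


def write_report(path: str | Path, report: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True))


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
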