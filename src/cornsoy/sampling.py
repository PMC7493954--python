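"""Geographically stratified training-set construction.

A square grid (50 km cells by default) is laid over the study extent and a
fixed number of points (250 by default) is drawn uniformly from each cell,
so that training data are spatially representative rather than clustered in
dense crop areas. Points are snapped to pixel centers, labelled per year,
filtered to crop classes with usable features, and split 80/20 within the
training years; records from held-back years are all tagged test.
"""

from __future__ import annotations

import logging
import math
from typing import Callable, Dict, List, Mapping, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from cornsoy.features import feature_names, HarmonicBasisSpec
from cornsoy.rng import substream
from cornsoy.synth import CROP_CLASSES, LabelRaster, NONCROP, RegionPartition

__all__ = [
    "GridCell",
    "make_grid",
    "sample_points",
    "attach_labels",
    "split",
    "class_frequency_report",
    "SAMPLE_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Non-feature columns of a SampleSet frame; features follow as f1..f20.
SAMPLE_COLUMNS: Tuple[str, ...] = ("x", "y", "year", "label", "cell_id", "region", "split")


class GridCell(NamedTuple):
    """Half-open axis-aligned cell [x0, x1) x [y0, y1)."""

    cell_id: int
    x0: float
    y0: float
    x1: float
    y1: float


def make_grid(extent: Tuple[float, float], cell_size: float) -> List[GridCell]:
    """Tile the extent (width, height in metres, origin 0) with square cells.

    Boundary cells are clipped to the extent (and may be partial); the
    half-open convention means every point of the extent falls in exactly
    one cell.
    """
    width, height = extent
    if width <= 0 or height <= 0:
        raise ValueError(f"extent must be positive, got {extent}")
    if cell_size <= 0:
        raise ValueError(f"cell_size must be positive, got {cell_size}")
    nx = math.ceil(width / cell_size)
    ny = math.ceil(height / cell_size)
    cells: List[GridCell] = []
    for j in range(ny):
        for i in range(nx):
            cells.append(
                GridCell(
                    cell_id=j * nx + i,
                    x0=i * cell_size,
                    y0=j * cell_size,
                    x1=min((i + 1) * cell_size, width),
                    y1=min((j + 1) * cell_size, height),
                )
            )
    return cells


def sample_points(
    cells: Sequence[GridCell],
    per_cell: int,
    predicate: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw ``per_cell`` uniform points in every cell, then filter to region.

    ``predicate(x, y) -> bool array`` defines membership in the study region
    (None keeps everything). Point counts per cell are equal before
    filtering — that is the stratification. Reproducible from ``seed``.
    """
    if per_cell < 1:
        raise ValueError(f"per_cell must be >= 1, got {per_cell}")
    rng = substream(seed, "sample_points")
    xs, ys, ids = [], [], []
    for cell in cells:
        u = rng.random((per_cell, 2))
        xs.append(cell.x0 + u[:, 0] * (cell.x1 - cell.x0))
        ys.append(cell.y0 + u[:, 1] * (cell.y1 - cell.y0))
        ids.append(np.full(per_cell, cell.cell_id, dtype=np.int64))
    df = pd.DataFrame(
        {
            "x": np.concatenate(xs),
            "y": np.concatenate(ys),
            "cell_id": np.concatenate(ids),
        }
    )
    if predicate is not None:
        keep = np.asarray(predicate(df["x"].to_numpy(), df["y"].to_numpy()), dtype=bool)
        df = df.loc[keep].reset_index(drop=True)
    return df


def attach_labels(
    points: pd.DataFrame,
    labels: Mapping[int, LabelRaster],
    features: Mapping[int, Tuple[np.ndarray, np.ndarray]],
    partition: Optional[RegionPartition] = None,
    spec: HarmonicBasisSpec = HarmonicBasisSpec(),
) -> pd.DataFrame:
    """Build one record per (point, year) with a crop label and usable features.

    ``features[year]`` is the ``(feature_raster, insufficient)`` pair from
    feature extraction. Points are snapped to the nearest pixel center
    (floor of coordinate / pixel size). Records whose label is non-crop,
    whose coordinate falls outside the raster, or whose features are flagged
    insufficient are dropped; out-of-bounds drops are counted in the log.
    """
    n_feat = 4 * spec.n_basis
    fnames = [f"f{i + 1}" for i in range(n_feat)]
    records = []
    dropped_oob = 0
    years = sorted(labels)
    for year in years:
        if year not in features:
            raise ValueError(f"no feature raster for year {year}")
        lab = labels[year]
        feat, insufficient = features[year]
        h, w = lab.shape
        px = lab.pixel_size
        col = np.floor(points["x"].to_numpy() / px).astype(np.int64)
        row = np.floor(points["y"].to_numpy() / px).astype(np.int64)
        inb = (col >= 0) & (col < w) & (row >= 0) & (row < h)
        dropped_oob += int((~inb).sum())
        col_i, row_i = col[inb], row[inb]
        sub = points.loc[inb].reset_index(drop=True)
        code = lab.data[row_i, col_i]
        ok = np.isin(code, np.array(CROP_CLASSES)) & ~insufficient[row_i, col_i]
        rec = pd.DataFrame(
            {
                "x": sub["x"].to_numpy()[ok],
                "y": sub["y"].to_numpy()[ok],
                "year": year,
                "label": code[ok].astype(int),
                "cell_id": sub["cell_id"].to_numpy()[ok],
                "region": (
                    partition.region_ids[row_i[ok], col_i[ok]].astype(int)
                    if partition is not None
                    else -1
                ),
                "split": "",
            }
        )
        feat_block = feat[row_i[ok], col_i[ok], :]
        for i, name in enumerate(fnames):
            rec[name] = feat_block[:, i]
        records.append(rec)
    if dropped_oob:
        logger.info("attach_labels: dropped %d out-of-bounds records", dropped_oob)
    if not records:
        return pd.DataFrame(columns=list(SAMPLE_COLUMNS) + fnames)
    return pd.concat(records, ignore_index=True)


def split(
    sample: pd.DataFrame,
    train_fraction: float,
    train_years: Sequence[int],
    test_years: Sequence[int],
    seed: int = 0,
) -> pd.DataFrame:
    """Tag records 'train'/'test'; the unit of splitting is the (point, year) record.

    Records from ``train_years`` are split ``train_fraction`` at random
    (floor rule on the training count); all records from ``test_years`` are
    tagged test. Records from years in neither set are dropped.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    overlap = set(train_years) & set(test_years)
    if overlap:
        raise ValueError(f"train and test year sets overlap: {sorted(overlap)}")
    keep = sample["year"].isin(list(train_years) + list(test_years))
    out = sample.loc[keep].reset_index(drop=True).copy()
    out["split"] = "test"
    train_idx = out.index[out["year"].isin(list(train_years))].to_numpy()
    rng = substream(seed, "split")
    perm = rng.permutation(train_idx)
    n_train = int(math.floor(train_fraction * train_idx.size))
    out.loc[perm[:n_train], "split"] = "train"
    out.loc[perm[n_train:], "split"] = "test"
    return out


def class_frequency_report(sample: pd.DataFrame) -> pd.DataFrame:
    """Per-region three-class sample composition, in percent.

    Mirrors the per-state crop-distribution tables used to interpret
    accuracy: skewed class mixtures bias accuracy upward.
    """
    counts = (
        sample.groupby(["region", "label"]).size().unstack(fill_value=0).astype(float)
    )
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    pct.columns = [f"pct_class_{c}" for c in pct.columns]
    pct["n_samples"] = counts.sum(axis=1).astype(int)
    return pct.reset_index()
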