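"""Configuration-driven orchestration: simulate -> extract -> sample ->
train -> predict -> mask -> validate.

The default configuration reproduces the production settings of the mapping
workflow — second-order harmonic basis with omega = 1.5, a 50 km sampling
grid with 250 points per cell, an 80/20 record split within the training
years, and 500-tree random forests trained per region — on a desk-scale
synthetic study area (64x64 pixels of ~3.1 km, four regions, five years,
with the most recent four years as training years and the earliest year
held back as a hindcast test, mirroring a train-recent / predict-past
design).

``run`` executes every stage and returns a machine-readable report;
re-running with the same configuration and seed reproduces the report
bit-for-bit. ``run_stress_pair`` re-runs the evaluation year under a named
degradation scenario and reports base/stress metric pairs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from cornsoy import io as csio
from cornsoy.classify import (
    ClassifierModel,
    CropMap,
    apply_mask,
    mask_year_for,
    predict_by_region,
    train,
)
from cornsoy.features import HarmonicBasisSpec, extract_features, feature_names
from cornsoy.metrics import (
    AREA_UNITS,
    ConfusionMatrix,
    build_area_table,
    confusion,
    overall_accuracy,
    area_trend,
    r_squared,
    rotation_fraction,
    squared_correlation,
    users_producers,
)
from cornsoy.rng import substream
from cornsoy.sampling import attach_labels, class_frequency_report, make_grid, sample_points, split
from cornsoy.synth import (
    CORN,
    CROP_CLASSES,
    NONCROP,
    OTHER,
    SOYBEAN,
    AcquisitionSchedule,
    LabelRaster,
    PhenologyParams,
    RegionPartition,
    SceneConfig,
    SceneLayout,
    SceneStack,
    default_phenologies,
    default_rotation,
    draw_classes,
    labels_from_classes,
    make_cropland_mask,
    make_partition,
    rotate_classes,
    scene_from_classes,
    stress_scenario,
)

__all__ = [
    "ConfigError",
    "PipelineConfig",
    "default_config",
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "save_config",
    "run",
    "run_stress_pair",
    "simulate_years",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """A configuration field violates its constraint."""


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, with production-faithful defaults."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    basis: HarmonicBasisSpec = field(default_factory=HarmonicBasisSpec)
    years: Tuple[int, ...] = (2014, 2015, 2016, 2017, 2018)
    train_years: Tuple[int, ...] = (2015, 2016, 2017, 2018)
    test_years: Tuple[int, ...] = (2014,)
    cell_size: float = 50_000.0
    per_cell: int = 250
    train_fraction: float = 0.8
    n_trees: int = 500
    mask_years: Tuple[int, ...] = (2014, 2016)
    mask_flip_rate: float = 0.02
    area_unit: str = "ha"
    seed: int = 0
    out_dir: Optional[str] = None

    def validate(self) -> None:
        """Raise ConfigError naming the offending field and constraint."""
        if self.n_trees < 1:
            raise ConfigError(f"n_trees: must be >= 1, got {self.n_trees}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError(
                f"train_fraction: must be in (0, 1), got {self.train_fraction}"
            )
        if self.cell_size <= 0:
            raise ConfigError(f"cell_size: must be > 0, got {self.cell_size}")
        if self.per_cell < 1:
            raise ConfigError(f"per_cell: must be >= 1, got {self.per_cell}")
        if not self.years:
            raise ConfigError("years: must be non-empty")
        if len(set(self.years)) != len(self.years):
            raise ConfigError("years: must be distinct")
        if not self.train_years:
            raise ConfigError("train_years: must be non-empty")
        for name, ys in (("train_years", self.train_years), ("test_years", self.test_years)):
            extra = set(ys) - set(self.years)
            if extra:
                raise ConfigError(f"{name}: {sorted(extra)} not in simulated years")
        if set(self.train_years) & set(self.test_years):
            raise ConfigError("train_years/test_years: year sets overlap")
        if not self.mask_years:
            raise ConfigError("mask_years: must be non-empty")
        if set(self.mask_years) - set(self.years):
            raise ConfigError(
                f"mask_years: {sorted(set(self.mask_years) - set(self.years))} "
                "not in simulated years"
            )
        if not 0.0 <= self.mask_flip_rate < 0.5:
            raise ConfigError(
                f"mask_flip_rate: must be in [0, 0.5), got {self.mask_flip_rate}"
            )
        if self.area_unit not in AREA_UNITS:
            raise ConfigError(
                f"area_unit: {self.area_unit!r} not one of {sorted(AREA_UNITS)}"
            )


def default_config(seed: int = 0, out_dir: Optional[str] = None) -> PipelineConfig:
    """Default study conditions: a 4-region scene whose crop composition
    varies by region (as state compositions do), Markov corn-soy rotation
    across years, 2% reference-label noise, and an 8-day revisit schedule
    with 40% cloud losses (median ~7 clear peak-season observations)."""
    layout = SceneLayout(
        width=64,
        height=64,
        pixel_area=3125.0 ** 2,
        mixture={CORN: 0.30, SOYBEAN: 0.30, OTHER: 0.25, NONCROP: 0.15},
        region_rows=2,
        region_cols=2,
        region_mixtures={
            0: {CORN: 0.45, SOYBEAN: 0.35, OTHER: 0.08, NONCROP: 0.12},
            1: {CORN: 0.35, SOYBEAN: 0.40, OTHER: 0.10, NONCROP: 0.15},
            2: {CORN: 0.25, SOYBEAN: 0.25, OTHER: 0.30, NONCROP: 0.20},
            3: {CORN: 0.15, SOYBEAN: 0.20, OTHER: 0.50, NONCROP: 0.15},
        },
        rotation=default_rotation(),
        label_noise=0.02,
    )
    scene = SceneConfig(
        phenologies=default_phenologies(),
        schedule=AcquisitionSchedule(revisit_days=8.0, cloud_prob=0.4),
        layout=layout,
    )
    return PipelineConfig(scene=scene, seed=seed, out_dir=out_dir)


# ---------------------------------------------------------------------------
# Config (de)serialization
# ---------------------------------------------------------------------------

def config_to_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    # mappings keyed by class id come out as {int: ...}; keep them JSON/YAML-safe
    scene = d["scene"]
    scene["phenologies"] = {
        int(k): {
            "class_id": p["class_id"],
            "peak_day": p["peak_day"],
            "peak_gcvi": p["peak_gcvi"],
            "season_width": p["season_width"],
            "base_reflectance": dict(p["base_reflectance"]),
            "amplitude": dict(p["amplitude"]),
            "noise_sd": dict(p["noise_sd"]),
        }
        for k, p in scene["phenologies"].items()
    }
    scene["schedule"]["blackout_windows"] = [
        list(w) for w in scene["schedule"]["blackout_windows"]
    ]
    layout = scene["layout"]
    layout["mixture"] = {int(k): float(v) for k, v in layout["mixture"].items()}
    if layout["region_mixtures"] is not None:
        layout["region_mixtures"] = {
            int(r): {int(k): float(v) for k, v in mix.items()}
            for r, mix in layout["region_mixtures"].items()
        }
    if layout["rotation"] is not None:
        layout["rotation"] = {
            int(a): {int(b): float(v) for b, v in row.items()}
            for a, row in layout["rotation"].items()
        }
    for key in ("years", "train_years", "test_years", "mask_years"):
        d[key] = list(d[key])
    return d


def config_from_dict(d: Mapping) -> PipelineConfig:
    d = dict(d)
    scene_d = dict(d.pop("scene"))
    phen = {
        int(k): PhenologyParams(**p) for k, p in scene_d["phenologies"].items()
    }
    sched_d = dict(scene_d["schedule"])
    sched_d["blackout_windows"] = tuple(
        tuple(w) for w in sched_d.get("blackout_windows", ())
    )
    layout_d = dict(scene_d["layout"])
    layout_d["mixture"] = {int(k): float(v) for k, v in layout_d["mixture"].items()}
    if layout_d.get("region_mixtures"):
        layout_d["region_mixtures"] = {
            int(r): {int(k): float(v) for k, v in mix.items()}
            for r, mix in layout_d["region_mixtures"].items()
        }
    if layout_d.get("rotation"):
        layout_d["rotation"] = {
            int(a): {int(b): float(v) for b, v in row.items()}
            for a, row in layout_d["rotation"].items()
        }
    scene = SceneConfig(
        phenologies=phen,
        schedule=AcquisitionSchedule(**sched_d),
        layout=SceneLayout(**layout_d),
    )
    basis = HarmonicBasisSpec(**d.pop("basis"))
    for key in ("years", "train_years", "test_years", "mask_years"):
        if key in d:
            d[key] = tuple(int(y) for y in d[key])
    return PipelineConfig(scene=scene, basis=basis, **d)


def save_config(path: str | Path, cfg: PipelineConfig) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))


def load_config(path: str | Path) -> PipelineConfig:
    cfg = config_from_dict(yaml.safe_load(Path(path).read_text()))
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _year_seed(cfg: PipelineConfig, year: int) -> int:
    return int(substream(cfg.seed, "year", year).integers(0, 2**31 - 1))


def simulate_years(
    cfg: PipelineConfig,
) -> Tuple[Dict[int, SceneStack], Dict[int, LabelRaster], Dict[int, np.ndarray], RegionPartition]:
    """Simulate every configured year with Markov crop rotation.

    Returns (scenes, labels, true class maps, partition). The first year's
    classes come from the layout mixture; later years advance under the
    layout's rotation table (or are drawn independently when no table is
    configured). Labels carry the configured label noise.
    """
    layout = cfg.scene.layout
    scenes: Dict[int, SceneStack] = {}
    labels: Dict[int, LabelRaster] = {}
    classes: Dict[int, np.ndarray] = {}
    prev: Optional[np.ndarray] = None
    for year in sorted(cfg.years):
        ys = _year_seed(cfg, year)
        if prev is None or layout.rotation is None:
            cls = draw_classes(layout, ys)
        else:
            cls = rotate_classes(prev, layout.rotation, ys)
        scenes[year] = scene_from_classes(cls, cfg.scene.phenologies, cfg.scene.schedule, ys)
        labels[year] = labels_from_classes(cls, layout, ys)
        classes[year] = cls
        prev = cls
        logger.info("simulate: year=%d seed=%d", year, ys)
    return scenes, labels, classes, make_partition(layout)


def extract_years(
    cfg: PipelineConfig, scenes: Mapping[int, SceneStack]
) -> Dict[int, Tuple[np.ndarray, np.ndarray]]:
    out = {}
    for year, stack in scenes.items():
        out[year] = extract_features(stack, cfg.basis)
        logger.info(
            "extract: year=%d insufficient=%d", year, int(out[year][1].sum())
        )
    return out


def sample_stage(
    cfg: PipelineConfig,
    labels: Mapping[int, LabelRaster],
    features: Mapping[int, Tuple[np.ndarray, np.ndarray]],
    partition: RegionPartition,
) -> pd.DataFrame:
    cells = make_grid(cfg.scene.layout.extent, cfg.cell_size)
    points = sample_points(cells, cfg.per_cell, predicate=None, seed=cfg.seed)
    sample = attach_labels(points, labels, features, partition, cfg.basis)
    tagged = split(sample, cfg.train_fraction, cfg.train_years, cfg.test_years, cfg.seed)
    logger.info(
        "sample: cells=%d points=%d records=%d train=%d",
        len(cells), len(points), len(tagged), int((tagged["split"] == "train").sum()),
    )
    return tagged


def train_stage(
    cfg: PipelineConfig, sample: pd.DataFrame, partition: RegionPartition
) -> Dict[int, ClassifierModel]:
    models = {}
    train_rows = sample[sample["split"] == "train"]
    for region in partition.regions:
        rows = train_rows[train_rows["region"] == region]
        models[region] = train(rows, region, cfg.n_trees, cfg.seed, cfg.basis)
        logger.info("train: region=%d n=%d trees=%d", region, len(rows), cfg.n_trees)
    return models


def predict_stage(
    cfg: PipelineConfig,
    models: Mapping[int, ClassifierModel],
    features: Mapping[int, Tuple[np.ndarray, np.ndarray]],
    labels: Mapping[int, LabelRaster],
    partition: RegionPartition,
) -> Tuple[Dict[int, CropMap], Dict[int, CropMap]]:
    """Predict every year's map, then apply the last-available cropland mask.

    Returns (pre-mask maps, masked maps). Masks derive from the mask-year's
    label raster with the configured staleness flip rate.
    """
    pixel_area = cfg.scene.layout.pixel_area
    masks = {
        y: make_cropland_mask(labels[y], cfg.mask_flip_rate, _year_seed(cfg, y))
        for y in cfg.mask_years
    }
    pre: Dict[int, CropMap] = {}
    post: Dict[int, CropMap] = {}
    for year in sorted(features):
        feats, insufficient = features[year]
        cmap = predict_by_region(models, feats, insufficient, partition, year, pixel_area)
        my = mask_year_for(year, cfg.mask_years)
        pre[year] = cmap
        post[year] = apply_mask(cmap, masks[my])
        logger.info("predict: year=%d mask_year=%d", year, my)
    return pre, post


# ---------------------------------------------------------------------------
# Validation / reporting
# ---------------------------------------------------------------------------

def _predict_records(
    models: Mapping[int, ClassifierModel], rows: pd.DataFrame, n_feat: int
) -> np.ndarray:
    cols = [f"f{i + 1}" for i in range(n_feat)]
    out = np.zeros(len(rows), dtype=np.int64)
    for region, sub in rows.groupby("region"):
        out[np.flatnonzero((rows["region"] == region).to_numpy())] = models[
            int(region)
        ].estimator.predict(sub[cols].to_numpy())
    return out


def _accuracy_block(
    models: Mapping[int, ClassifierModel], rows: pd.DataFrame, n_feat: int
) -> dict:
    if len(rows) == 0:
        return {"n": 0, "overall_accuracy": None}
    pred = _predict_records(models, rows, n_feat)
    ref = rows["label"].to_numpy()
    cm = np.zeros((3, 3), dtype=np.int64)
    idx = {c: i for i, c in enumerate(CROP_CLASSES)}
    for rc, pc in zip(ref, pred):
        cm[idx[rc], idx[pc]] += 1
    cmat = ConfusionMatrix(counts=cm)
    block = {
        "n": int(len(rows)),
        "overall_accuracy": overall_accuracy(cmat),
        "confusion": cm.tolist(),
        "users_producers": {},
    }
    for c in CROP_CLASSES:
        ua, pa = users_producers(cmat, c)
        block["users_producers"][str(c)] = [ua, pa]
    per_region = {}
    for region, sub in rows.groupby("region"):
        p = _predict_records(models, sub.reset_index(drop=True), n_feat)
        per_region[str(int(region))] = float((p == sub["label"].to_numpy()).mean())
    block["per_region_accuracy"] = per_region
    return block


def validate_stage(
    cfg: PipelineConfig,
    sample: pd.DataFrame,
    models: Mapping[int, ClassifierModel],
    pre_maps: Mapping[int, CropMap],
    post_maps: Mapping[int, CropMap],
    labels: Mapping[int, LabelRaster],
    features: Mapping[int, Tuple[np.ndarray, np.ndarray]],
    partition: RegionPartition,
) -> dict:
    """Compute every reported statistic from the run's artifacts."""
    n_feat = 4 * cfg.basis.n_basis
    held_out = sample[(sample["split"] == "test") & sample["year"].isin(cfg.train_years)]
    hindcast = sample[sample["year"].isin(cfg.test_years)]

    report: dict = {
        "held_out": _accuracy_block(models, held_out.reset_index(drop=True), n_feat),
        "hindcast": _accuracy_block(models, hindcast.reset_index(drop=True), n_feat),
    }

    # map-level agreement with the (noisy) reference labels
    map_acc = {}
    for year in sorted(post_maps):
        cm = confusion(post_maps[year], labels[year])
        map_acc[str(year)] = {
            "overall_accuracy": overall_accuracy(cm),
            "n_compared": cm.total,
            "n_excluded": cm.excluded,
        }
    report["map_accuracy"] = map_acc

    # county-level area agreement
    table = build_area_table(dict(post_maps), dict(labels), partition, cfg.area_unit)
    area_r2 = {}
    for cls, cname in ((CORN, "corn"), (SOYBEAN, "soybean")):
        for tag, years in (("train_years", cfg.train_years), ("test_years", cfg.test_years)):
            sub = table[(table["class_code"] == cls) & table["year"].isin(years)]
            area_r2[f"{cname}_{tag}"] = (
                r_squared(sub["reference_area"], sub["predicted_area"])
                if len(sub) >= 2
                else None
            )
    report["area_r2"] = area_r2
    report["area_table"] = table.to_dict(orient="list")

    # rotation statistics: predicted vs label-derived, per region and year pair
    years_sorted = sorted(post_maps)
    rot_rows = []
    for prev_y, curr_y in zip(years_sorted[:-1], years_sorted[1:]):
        pred_rot = rotation_fraction(post_maps[prev_y], post_maps[curr_y], partition)
        ref_prev = CropMap(
            data=labels[prev_y].data, year=prev_y, pixel_area=labels[prev_y].pixel_area
        )
        ref_curr = CropMap(
            data=labels[curr_y].data, year=curr_y, pixel_area=labels[curr_y].pixel_area
        )
        ref_rot = rotation_fraction(ref_prev, ref_curr, partition)
        for p, r in zip(pred_rot, ref_rot):
            rot_rows.append(
                {
                    "region": p.region,
                    "year_prev": prev_y,
                    "year_curr": curr_y,
                    "predicted_fraction": p.fraction,
                    "reference_fraction": r.fraction,
                }
            )
    report["rotation"] = {"records": rot_rows}
    defined = [
        (r["reference_fraction"], r["predicted_fraction"])
        for r in rot_rows
        if r["reference_fraction"] is not None and r["predicted_fraction"] is not None
    ]
    if len(defined) >= 2:
        ref_v, pred_v = zip(*defined)
        report["rotation"]["squared_correlation"] = squared_correlation(ref_v, pred_v)
        report["rotation"]["r_squared"] = r_squared(ref_v, pred_v)
    else:
        report["rotation"]["squared_correlation"] = None
        report["rotation"]["r_squared"] = None

    # linear area trends per region, corn and soy, predicted and reference
    trends = {}
    for cls, cname in ((CORN, "corn"), (SOYBEAN, "soybean")):
        sub = table[table["class_code"] == cls]
        trends[cname] = {}
        for region in partition.regions:
            rsub = sub[sub["region"] == region].sort_values("year")
            trends[cname][str(int(region))] = {
                "predicted_slope": area_trend(rsub["year"], rsub["predicted_area"]),
                "reference_slope": area_trend(rsub["year"], rsub["reference_area"]),
            }
    report["trends"] = trends

    report["insufficiency"] = {
        str(y): int(features[y][1].sum()) for y in sorted(features)
    }
    report["class_frequencies"] = class_frequency_report(sample).to_dict(orient="list")
    return report


# ---------------------------------------------------------------------------
# One-shot runs
# ---------------------------------------------------------------------------

def run(cfg: PipelineConfig) -> dict:
    """Execute all stages; return (and optionally write) the run report."""
    cfg.validate()
    scenes, labels, classes, partition = simulate_years(cfg)
    features = extract_years(cfg, scenes)
    sample = sample_stage(cfg, labels, features, partition)
    models = train_stage(cfg, sample, partition)
    pre_maps, post_maps = predict_stage(cfg, models, features, labels, partition)
    report = validate_stage(
        cfg, sample, models, pre_maps, post_maps, labels, features, partition
    )
    report["config"] = config_to_dict(cfg)
    report["seed"] = cfg.seed

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_config(out / "config.yaml", cfg)
        for year in cfg.years:
            csio.write_scene(out / "scenes" / str(year), scenes[year])
            csio.write_labels(out / "labels" / f"{year}.tif", labels[year])
            csio.write_features(
                out / "features" / f"{year}.tif",
                features[year][0],
                features[year][1],
                feature_names(cfg.basis),
            )
            csio.write_map(out / "maps" / f"{year}.tif", post_maps[year])
        csio.write_partition(out / "partition.tif", partition)
        csio.write_samples(out / "samples.csv", sample)
        for region, model in models.items():
            csio.write_model(out / "models" / f"region_{region}.joblib", model)
        csio.write_report(out / "report.json", report)
    return report


def _stress_eval_year(cfg: PipelineConfig) -> int:
    return sorted(cfg.test_years)[0] if cfg.test_years else sorted(cfg.years)[0]


def run_stress_pair(cfg: PipelineConfig, scenario: str) -> dict:
    """Base-vs-stress comparison at matched seeds.

    For ``midseason_blackout`` and ``delayed_planting`` the degradation is
    applied at prediction time only: models train on base conditions, the
    evaluation year's scene is re-simulated (same true classes, same seed)
    under the stressed configuration, and confusion against the true labels
    is compared. For ``low_revisit`` the whole pipeline re-runs under the
    stressed schedule and held-out accuracies are compared.
    """
    cfg.validate()
    stressed_scene = stress_scenario(scenario, cfg.scene)

    if scenario == "low_revisit":
        base_report = run(dataclasses.replace(cfg, out_dir=None))
        stress_cfg = dataclasses.replace(cfg, scene=stressed_scene, out_dir=None)
        stress_report = run(stress_cfg)
        return {
            "scenario": scenario,
            "base": {
                "held_out_overall_accuracy": base_report["held_out"]["overall_accuracy"]
            },
            "stress": {
                "held_out_overall_accuracy": stress_report["held_out"]["overall_accuracy"]
            },
        }

    scenes, labels, classes, partition = simulate_years(cfg)
    features = extract_years(cfg, scenes)
    sample = sample_stage(cfg, labels, features, partition)
    models = train_stage(cfg, sample, partition)

    eval_year = _stress_eval_year(cfg)
    ys = _year_seed(cfg, eval_year)
    stress_stack = scene_from_classes(
        classes[eval_year], stressed_scene.phenologies, stressed_scene.schedule, ys
    )
    stress_features = {eval_year: extract_features(stress_stack, cfg.basis)}

    def _confusion_for(feats) -> dict:
        f, insufficient = feats
        cmap = predict_by_region(
            models, f, insufficient, partition, eval_year, cfg.scene.layout.pixel_area
        )
        cm = confusion(cmap, labels[eval_year])
        return {
            "overall_accuracy": overall_accuracy(cm),
            "soy_predicted_corn": cm.count(SOYBEAN, CORN),
            "corn_predicted_soy": cm.count(CORN, SOYBEAN),
            "n_compared": cm.total,
            "n_insufficient": int(insufficient.sum()),
        }

    return {
        "scenario": scenario,
        "eval_year": eval_year,
        "base": _confusion_for(features[eval_year]),
        "stress": _confusion_for(stress_features[eval_year]),
    }
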