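"""Synthetic multispectral scene simulator for corn/soy phenology.

Generates Landsat-like raster time-series cubes with per-observation cloud
losses, categorical label rasters, cropland masks, and synthetic "county"
partitions, with the statistical structure the classification pipeline
assumes: soybean peaks later and higher in GCVI than corn, an early-peaking
"other" (winter-cereal-like) class, 8–16-day revisit with random invalid
observations, and optional label noise emulating imperfect reference maps.

Class codes follow the crop-data-layer convention:
1 = corn, 5 = soybean, 9 = other crop, 255 = non-crop, 0 = unclassified.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from cornsoy.rng import substream

__all__ = [
    "BANDS",
    "CORN",
    "SOYBEAN",
    "OTHER",
    "NONCROP",
    "UNCLASSIFIED",
    "CROP_CLASSES",
    "PEAK_SEASON",
    "PhenologyParams",
    "AcquisitionSchedule",
    "SceneStack",
    "LabelRaster",
    "RegionPartition",
    "SceneLayout",
    "SceneConfig",
    "default_phenologies",
    "default_rotation",
    "phenology_curve",
    "seasonal_bump",
    "draw_classes",
    "rotate_classes",
    "labels_from_classes",
    "make_partition",
    "scene_from_classes",
    "simulate_scene",
    "stress_scenario",
    "make_cropland_mask",
    "median_valid_count",
    "STRESS_SCENARIOS",
]

#: Surface-reflectance band names, in storage order.
BANDS: Tuple[str, ...] = ("Blue", "Green", "Red", "NIR", "SWIR1", "SWIR2")

CORN, SOYBEAN, OTHER, NONCROP, UNCLASSIFIED = 1, 5, 9, 255, 0
CROP_CLASSES: Tuple[int, ...] = (CORN, SOYBEAN, OTHER)
LEGAL_LABELS: Tuple[int, ...] = (CORN, SOYBEAN, OTHER, NONCROP)

#: June 1 – August 31 as fractions of the year: the key growing months used
#: when counting clear observations.
PEAK_SEASON: Tuple[float, float] = (151.0 / 365.0, 243.0 / 365.0)


# ---------------------------------------------------------------------------
# Phenology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenologyParams:
    """Seasonal reflectance model for one land-cover class.

    Each band follows ``base + amplitude * bump(t)`` where ``bump`` is a
    smooth unimodal curve peaking at ``peak_day`` (fraction of year) with
    width ``season_width``. ``peak_gcvi`` is the GCVI value implied at the
    seasonal peak; defaults derive the NIR amplitude from it so the
    green/NIR ratio hits the stated peak exactly.

    Parameters are unitless surface reflectances in [0, 1] except
    ``peak_day``/``season_width`` (fractions of a year) and ``peak_gcvi``
    (unitless index value).
    """

    class_id: int
    peak_day: float
    peak_gcvi: float
    season_width: float
    base_reflectance: Mapping[str, float]
    amplitude: Mapping[str, float]
    noise_sd: Mapping[str, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.peak_day < 1.0:
            raise ValueError(f"peak_day must be in [0, 1), got {self.peak_day}")
        if self.season_width <= 0.0:
            raise ValueError(f"season_width must be > 0, got {self.season_width}")
        if self.peak_gcvi <= 0.0:
            raise ValueError(f"peak_gcvi must be > 0, got {self.peak_gcvi}")
        for band in BANDS:
            for mapping, what in (
                (self.base_reflectance, "base_reflectance"),
                (self.amplitude, "amplitude"),
                (self.noise_sd, "noise_sd"),
            ):
                if band not in mapping:
                    raise ValueError(f"{what} missing band {band!r}")
            base = self.base_reflectance[band]
            if not 0.0 < base < 1.0:
                raise ValueError(
                    f"base_reflectance[{band!r}] must be in (0, 1), got {base}"
                )


def seasonal_bump(t: np.ndarray | float, peak_day: float, width: float):
    """Gaussian bump on the circular year: 1 at ``peak_day``, -> 0 off-season.

    Uses circular distance so curves behave sensibly near the year boundary.
    """
    t = np.asarray(t, dtype=float)
    d = np.abs(t - peak_day)
    d = np.minimum(d, 1.0 - d)
    return np.exp(-0.5 * (d / width) ** 2)


def phenology_curve(params: PhenologyParams, band: str, t):
    """Noise-free reflectance of ``band`` at fractional-year time(s) ``t``."""
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}; expected one of {BANDS}")
    bump = seasonal_bump(t, params.peak_day, params.season_width)
    return params.base_reflectance[band] + params.amplitude[band] * bump


# Off-season (bare soil / residue) reflectance shared by the crop classes.
_SOIL = {
    "Blue": 0.06, "Green": 0.10, "Red": 0.12,
    "NIR": 0.18, "SWIR1": 0.28, "SWIR2": 0.22,
}
# Change from soil to a dense green canopy, before per-class scaling.
_CANOPY_SWING = {
    "Blue": -0.030, "Green": 0.000, "Red": -0.070,
    "NIR": 0.0,  # derived from peak_gcvi below
    "SWIR1": -0.120, "SWIR2": -0.130,
}
_NOISE_SD = {
    "Blue": 0.010, "Green": 0.010, "Red": 0.010,
    "NIR": 0.020, "SWIR1": 0.020, "SWIR2": 0.020,
}


def _crop_params(
    class_id: int,
    peak_day: float,
    peak_gcvi: float,
    season_width: float,
    vegetation_fraction: float = 1.0,
) -> PhenologyParams:
    """Build a parameter set whose peak GCVI equals ``peak_gcvi`` exactly."""
    amp = {b: _CANOPY_SWING[b] * vegetation_fraction for b in BANDS}
    green_peak = _SOIL["Green"] + amp["Green"]
    amp["NIR"] = (1.0 + peak_gcvi) * green_peak - _SOIL["NIR"]
    return PhenologyParams(
        class_id=class_id,
        peak_day=peak_day,
        peak_gcvi=peak_gcvi,
        season_width=season_width,
        base_reflectance=dict(_SOIL),
        amplitude=amp,
        noise_sd=dict(_NOISE_SD),
    )


def default_phenologies() -> Dict[int, PhenologyParams]:
    """Default per-class phenologies.

    Encodes the ordering facts the pipeline relies on: soybean peaks later
    (early August vs mid July) and higher in GCVI than corn; "other" is an
    early-peaking, lower-amplitude winter-cereal-like curve; non-crop is a
    broad, low-contrast grass/forest-like curve.
    """
    return {
        CORN: _crop_params(CORN, peak_day=0.55, peak_gcvi=2.0, season_width=0.09),
        SOYBEAN: _crop_params(
            SOYBEAN, peak_day=0.60, peak_gcvi=2.6, season_width=0.08
        ),
        OTHER: _crop_params(
            OTHER, peak_day=0.42, peak_gcvi=1.5, season_width=0.11,
            vegetation_fraction=0.7,
        ),
        NONCROP: _crop_params(
            NONCROP, peak_day=0.50, peak_gcvi=1.2, season_width=0.22,
            vegetation_fraction=0.5,
        ),
    }


def default_rotation() -> Dict[int, Dict[int, float]]:
    """Year-to-year crop transition probabilities (Midwest-like).

    Corn-soy alternation dominates; "other" is sticky; non-crop never
    transitions (handled outside this table).
    """
    return {
        CORN: {CORN: 0.35, SOYBEAN: 0.55, OTHER: 0.10},
        SOYBEAN: {CORN: 0.65, SOYBEAN: 0.25, OTHER: 0.10},
        OTHER: {CORN: 0.15, SOYBEAN: 0.15, OTHER: 0.70},
    }


# ---------------------------------------------------------------------------
# Acquisition and containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionSchedule:
    """Nominal revisit plus stochastic cloud losses and hard blackout windows.

    ``revisit_days`` is the nominal days between acquisitions (8 when two
    satellites operate, 16 for one); ``cloud_prob`` is the per-observation
    probability that a pixel is occluded; ``blackout_windows`` are
    [start, end) fractional-year intervals with no valid observations at all.
    """

    revisit_days: float = 8.0
    cloud_prob: float = 0.4
    blackout_windows: Tuple[Tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.revisit_days <= 0:
            raise ValueError(f"revisit_days must be > 0, got {self.revisit_days}")
        if not 0.0 <= self.cloud_prob < 1.0:
            raise ValueError(f"cloud_prob must be in [0, 1), got {self.cloud_prob}")
        for w in self.blackout_windows:
            if not (0.0 <= w[0] < w[1] <= 1.0):
                raise ValueError(f"blackout window {w} not within [0, 1)")

    def times(self) -> np.ndarray:
        """Fractional-year acquisition timestamps for one calendar year."""
        step = self.revisit_days / 365.0
        n = int(np.floor((1.0 - 0.5 * step) / step)) + 1
        return (np.arange(n) + 0.5) * step


@dataclass
class SceneStack:
    """One year of observations: times, band values, per-obs validity.

    ``values`` has shape (T, B, H, W); ``valid`` has shape (T, H, W).
    Invalid observations carry no information and must never be read
    downstream.
    """

    times: np.ndarray
    bands: Tuple[str, ...]
    values: np.ndarray
    valid: np.ndarray

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape[2], self.values.shape[3]

    def band_index(self, band: str) -> int:
        try:
            return self.bands.index(band)
        except ValueError:
            raise ValueError(
                f"band {band!r} not in stack; have {self.bands}"
            ) from None

    def series(self, row: int, col: int, band: str) -> Tuple[np.ndarray, np.ndarray]:
        """(t, v) of the *valid* observations of one pixel and band."""
        ok = self.valid[:, row, col]
        b = self.band_index(band)
        return self.times[ok], self.values[ok, b, row, col]


@dataclass
class LabelRaster:
    """Categorical reference map with codes {1, 5, 9, 255}."""

    data: np.ndarray
    pixel_area: float  # m^2 per pixel

    def __post_init__(self) -> None:
        if self.pixel_area <= 0:
            raise ValueError(f"pixel_area must be > 0, got {self.pixel_area}")
        bad = np.setdiff1d(np.unique(self.data), np.array(LEGAL_LABELS))
        if bad.size:
            raise ValueError(f"illegal label codes {bad.tolist()}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.data.shape

    @property
    def pixel_size(self) -> float:
        """Pixel edge length in metres (pixels are square)."""
        return float(np.sqrt(self.pixel_area))


@dataclass
class RegionPartition:
    """Synthetic 'county' membership: every pixel in exactly one region."""

    region_ids: np.ndarray
    regions: Tuple[int, ...]

    def __post_init__(self) -> None:
        present = np.unique(self.region_ids)
        if not np.isin(present, np.array(self.regions)).all():
            raise ValueError("region_ids contains ids not in the region list")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.region_ids.shape

    def mask(self, region: int) -> np.ndarray:
        return self.region_ids == region


@dataclass(frozen=True)
class SceneLayout:
    """Raster geometry and class composition of a simulated scene.

    ``mixture`` gives whole-scene class proportions; ``region_mixtures``
    (optional, keyed by region id) lets synthetic counties differ in crop
    composition the way real states do. ``rotation`` is a crop transition
    table used when simulating consecutive years; non-crop pixels are static.
    ``label_noise`` flips that fraction of crop labels to another crop class,
    emulating reference-map error.
    """

    width: int = 64
    height: int = 64
    pixel_area: float = 3125.0 ** 2
    mixture: Mapping[int, float] = field(
        default_factory=lambda: {CORN: 0.35, SOYBEAN: 0.30, OTHER: 0.20, NONCROP: 0.15}
    )
    region_rows: int = 2
    region_cols: int = 2
    region_mixtures: Optional[Mapping[int, Mapping[int, float]]] = None
    rotation: Optional[Mapping[int, Mapping[int, float]]] = None
    label_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("raster size must be at least 1x1")
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be > 0")
        if not 0.0 <= self.label_noise < 1.0:
            raise ValueError("label_noise must be in [0, 1)")
        for mix in self._all_mixtures():
            s = sum(mix.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"class mixture must sum to 1, got {s}")
            unknown = set(mix) - set(LEGAL_LABELS)
            if unknown:
                raise ValueError(f"mixture contains unknown classes {unknown}")

    def _all_mixtures(self) -> List[Mapping[int, float]]:
        out: List[Mapping[int, float]] = [self.mixture]
        if self.region_mixtures:
            out.extend(self.region_mixtures.values())
        return out

    @property
    def n_regions(self) -> int:
        return self.region_rows * self.region_cols

    @property
    def extent(self) -> Tuple[float, float]:
        """(width, height) of the scene in metres."""
        px = float(np.sqrt(self.pixel_area))
        return self.width * px, self.height * px


@dataclass(frozen=True)
class SceneConfig:
    """Bundle of everything needed to simulate one scene."""

    phenologies: Mapping[int, PhenologyParams] = field(
        default_factory=default_phenologies
    )
    schedule: AcquisitionSchedule = field(default_factory=AcquisitionSchedule)
    layout: SceneLayout = field(default_factory=SceneLayout)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def make_partition(layout: SceneLayout) -> RegionPartition:
    """Tile the raster into region_rows x region_cols rectangular 'counties'."""
    rows = np.minimum(
        (np.arange(layout.height) * layout.region_rows) // layout.height,
        layout.region_rows - 1,
    )
    cols = np.minimum(
        (np.arange(layout.width) * layout.region_cols) // layout.width,
        layout.region_cols - 1,
    )
    ids = rows[:, None] * layout.region_cols + cols[None, :]
    return RegionPartition(
        region_ids=ids.astype(np.int32), regions=tuple(range(layout.n_regions))
    )


def draw_classes(layout: SceneLayout, seed: int) -> np.ndarray:
    """Draw the per-pixel true class map from the layout's mixture(s)."""
    rng = substream(seed, "classes")
    u = rng.random((layout.height, layout.width))
    out = np.empty((layout.height, layout.width), dtype=np.uint8)
    partition = make_partition(layout)
    for region in partition.regions:
        mix = dict(layout.mixture)
        if layout.region_mixtures and region in layout.region_mixtures:
            mix = dict(layout.region_mixtures[region])
        classes = sorted(mix)
        edges = np.cumsum([mix[c] for c in classes])
        sel = partition.mask(region)
        idx = np.searchsorted(edges, u[sel], side="right")
        idx = np.minimum(idx, len(classes) - 1)
        out[sel] = np.array(classes, dtype=np.uint8)[idx]
    return out


def rotate_classes(
    classes: np.ndarray,
    transition: Mapping[int, Mapping[int, float]],
    seed: int,
) -> np.ndarray:
    """Advance the true class map one year under a crop transition table."""
    rng = substream(seed, "rotation")
    u = rng.random(classes.shape)
    out = classes.copy()
    for prev, row in transition.items():
        nxt = sorted(row)
        edges = np.cumsum([row[c] for c in nxt])
        if abs(edges[-1] - 1.0) > 1e-9:
            raise ValueError(f"transition row for class {prev} must sum to 1")
        sel = classes == prev
        idx = np.minimum(np.searchsorted(edges, u[sel], side="right"), len(nxt) - 1)
        out[sel] = np.array(nxt, dtype=np.uint8)[idx]
    return out


def labels_from_classes(
    classes: np.ndarray, layout: SceneLayout, seed: int
) -> LabelRaster:
    """Reference labels = true classes, with ``label_noise`` crop flips."""
    data = classes.copy()
    if layout.label_noise > 0.0:
        rng = substream(seed, "label_noise")
        crop = np.isin(data, np.array(CROP_CLASSES))
        flip = crop & (rng.random(data.shape) < layout.label_noise)
        # flip to one of the two other crop classes, uniformly
        others = {
            c: np.array([o for o in CROP_CLASSES if o != c], dtype=np.uint8)
            for c in CROP_CLASSES
        }
        pick = rng.integers(0, 2, size=data.shape)
        for c in CROP_CLASSES:
            sel = flip & (classes == c)
            data[sel] = others[c][pick[sel]]
    return LabelRaster(data=data, pixel_area=layout.pixel_area)


def scene_from_classes(
    classes: np.ndarray,
    phenologies: Mapping[int, PhenologyParams],
    schedule: AcquisitionSchedule,
    seed: int,
) -> SceneStack:
    """Sample every pixel's phenology curve at the schedule's times.

    Additive Gaussian observation noise per band, truncated at zero;
    validity flags drawn per observation, then blackout windows zeroed.
    """
    times = schedule.times()
    if times.size == 0:
        raise ValueError("acquisition schedule yields no observation times")
    h, w = classes.shape
    t_count, b_count = times.size, len(BANDS)

    present = np.unique(classes)
    missing = [int(c) for c in present if int(c) not in phenologies]
    if missing:
        raise ValueError(f"no phenology parameters for classes {missing}")

    values = np.empty((t_count, b_count, h, w), dtype=np.float32)
    noise_scale = np.empty((b_count, h, w), dtype=np.float32)
    for c in present:
        p = phenologies[int(c)]
        sel = classes == c
        for bi, band in enumerate(BANDS):
            curve = phenology_curve(p, band, times).astype(np.float32)
            values[:, bi, sel] = curve[:, None]
            noise_scale[bi, sel] = p.noise_sd[band]

    rng = substream(seed, "noise")
    values += rng.standard_normal(values.shape, dtype=np.float32) * noise_scale
    np.clip(values, 0.0, 2.0, out=values)

    rng_c = substream(seed, "clouds")
    valid = rng_c.random((t_count, h, w)) >= schedule.cloud_prob
    for start, end in schedule.blackout_windows:
        valid[(times >= start) & (times < end)] = False
    return SceneStack(times=times, bands=BANDS, values=values, valid=valid)


def simulate_scene(
    phenologies: Mapping[int, PhenologyParams],
    schedule: AcquisitionSchedule,
    layout: SceneLayout,
    seed: int,
) -> Tuple[SceneStack, LabelRaster, RegionPartition]:
    """Simulate one year: observation cube, label raster, region partition.

    Fully reproducible from ``seed``; each stochastic component draws from
    its own named substream.
    """
    classes = draw_classes(layout, seed)
    stack = scene_from_classes(classes, phenologies, schedule, seed)
    labels = labels_from_classes(classes, layout, seed)
    return stack, labels, make_partition(layout)


# ---------------------------------------------------------------------------
# Stress scenarios and masks
# ---------------------------------------------------------------------------

STRESS_SCENARIOS: Tuple[str, ...] = (
    "midseason_blackout",
    "delayed_planting",
    "low_revisit",
)


def stress_scenario(name: str, base: SceneConfig) -> SceneConfig:
    """Return ``base`` modified to emulate a documented failure mode.

    - ``midseason_blackout``: no valid observations from roughly July 1 to
      September 30 (widened if needed to cover both corn and soybean peaks),
      as when a satellite track acquires no clear mid-season imagery.
    - ``delayed_planting``: corn's peak shifts 70% of the way toward
      soybean's, as in a late-planting year where the two phenologies merge.
    - ``low_revisit``: coarser revisit and heavier cloud losses so the
      median valid count in the June–August peak season drops to ~4, as in
      a single-satellite year.
    """
    if name == "midseason_blackout":
        corn_peak = base.phenologies[CORN].peak_day
        soy_peak = base.phenologies[SOYBEAN].peak_day
        lo = min(181.0 / 365.0, min(corn_peak, soy_peak) - 0.02)
        hi = max(273.0 / 365.0, max(corn_peak, soy_peak) + 0.02)
        windows = base.schedule.blackout_windows + ((lo, hi),)
        return dataclasses.replace(
            base,
            schedule=dataclasses.replace(base.schedule, blackout_windows=windows),
        )
    if name == "delayed_planting":
        corn = base.phenologies[CORN]
        soy = base.phenologies[SOYBEAN]
        shifted = dataclasses.replace(
            corn, peak_day=corn.peak_day + 0.7 * (soy.peak_day - corn.peak_day)
        )
        phen = dict(base.phenologies)
        phen[CORN] = shifted
        return dataclasses.replace(base, phenologies=phen)
    if name == "low_revisit":
        return dataclasses.replace(
            base,
            schedule=dataclasses.replace(
                base.schedule, revisit_days=12.0, cloud_prob=0.45
            ),
        )
    raise ValueError(
        f"unknown stress scenario {name!r}; valid scenarios are {STRESS_SCENARIOS}"
    )


def median_valid_count(
    stack: SceneStack, window: Tuple[float, float] = PEAK_SEASON
) -> float:
    """Median over pixels of the valid-observation count within ``window``."""
    sel = (stack.times >= window[0]) & (stack.times <= window[1])
    counts = stack.valid[sel].sum(axis=0)
    return float(np.median(counts))


def make_cropland_mask(
    label: LabelRaster, flip_rate: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Boolean cropland mask from a label raster, with optional staleness.

    Crop classes map to True, non-crop to False; ``flip_rate`` of pixels are
    toggled to emulate an out-of-date land-cover product.
    """
    if not 0.0 <= flip_rate < 0.5:
        raise ValueError(f"flip_rate must be in [0, 0.5), got {flip_rate}")
    mask = label.data != NONCROP
    if flip_rate > 0.0:
        rng = substream(seed, "mask_flips")
        flips = rng.random(mask.shape) < flip_rate
        mask = mask ^ flips
    return mask
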