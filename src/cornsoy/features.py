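"""Harmonic-regression features and the candidate-feature registry.

Each band or vegetation index at a pixel is treated as a time-dependent
function f(t) over the calendar year (t in [0, 1)) and summarized by
ordinary least squares on a truncated Fourier basis:

    f(t) = c + sum_{k=1..n} [ a_k cos(2 pi k w t) + b_k sin(2 pi k w t) ]

with order n = 2 and period control w = 1.5 by default, giving 5
coefficients per band. The final feature vector stacks NIR, SWIR1, SWIR2,
and GCVI (= NIR/Green - 1), band-major in the frozen coefficient order
[c, a1, b1, a2, b2] — 20 features.

A fit needs at least 2n+1 valid observations and a full-rank design;
otherwise the pixel is flagged insufficient rather than fitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import scipy.linalg

from cornsoy.synth import SceneStack

__all__ = [
    "FEATURE_BANDS",
    "HarmonicBasisSpec",
    "BandTimeSeries",
    "RegistryEntry",
    "FeatureRegistry",
    "gcvi",
    "design_matrix",
    "fit_harmonic",
    "evaluate_harmonic",
    "extract_features",
    "feature_names",
    "registry",
]

#: Bands/indices entering the final feature vector, in storage order.
FEATURE_BANDS: Tuple[str, ...] = ("NIR", "SWIR1", "SWIR2", "GCVI")


@dataclass(frozen=True)
class HarmonicBasisSpec:
    """Order and period control of the harmonic basis (defaults n=2, w=1.5)."""

    n: int = 2
    omega: float = 1.5

    def __post_init__(self) -> None:
        if self.n < 1 or int(self.n) != self.n:
            raise ValueError(f"harmonic order n must be an integer >= 1, got {self.n}")

    @property
    def n_basis(self) -> int:
        """Number of basis functions (intercept + cos/sin pairs) = 2n+1."""
        return 2 * self.n + 1

    def coefficient_names(self) -> Tuple[str, ...]:
        names = ["c"]
        for k in range(1, self.n + 1):
            names += [f"a{k}", f"b{k}"]
        return tuple(names)


class BandTimeSeries(NamedTuple):
    """Valid observations of one band at one pixel."""

    t: np.ndarray
    v: np.ndarray


def gcvi(nir, green):
    """Green Chlorophyll Vegetation Index: NIR/Green - 1.

    Observations with green <= 0 are marked invalid (NaN) rather than
    raising, so one bad date does not void a pixel; callers exclude
    non-finite values from fitting.
    """
    nir = np.asarray(nir, dtype=float)
    green = np.asarray(green, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = nir / green - 1.0
    out = np.where(green > 0.0, out, np.nan)
    return float(out) if out.ndim == 0 else out


def design_matrix(t: np.ndarray, spec: HarmonicBasisSpec) -> np.ndarray:
    """Harmonic design: [1, cos(2pi w t), sin(2pi w t), cos(4pi w t), ...].

    Column order matches the frozen coefficient order [c, a1, b1, a2, b2].
    """
    t = np.asarray(t, dtype=float)
    cols = [np.ones_like(t)]
    for k in range(1, spec.n + 1):
        ang = 2.0 * np.pi * k * spec.omega * t
        cols.append(np.cos(ang))
        cols.append(np.sin(ang))
    return np.column_stack(cols)


def fit_harmonic(
    t: np.ndarray,
    v: np.ndarray,
    spec: HarmonicBasisSpec = HarmonicBasisSpec(),
) -> Optional[np.ndarray]:
    """Least-squares harmonic coefficients, or None if insufficient.

    Non-finite observations are excluded. Returns None (the "insufficient"
    sentinel) when fewer than 2n+1 valid observations remain or the design
    is rank-deficient (e.g. duplicate timestamps only); never raises for
    degenerate data. Observations are sorted by time first, so the result
    is bit-identical under reordering.

    Uses QR-based least squares (LAPACK gelsy) rather than normal
    equations for numerical robustness.
    """
    t = np.asarray(t, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if t.size != v.size:
        raise ValueError(f"t and v lengths differ: {t.size} vs {v.size}")
    ok = np.isfinite(v) & np.isfinite(t)
    t, v = t[ok], v[ok]
    if t.size < spec.n_basis:
        return None
    order = np.argsort(t, kind="stable")
    x = design_matrix(t[order], spec)
    coef, _, rank = scipy.linalg.lstsq(x, v[order], lapack_driver="gelsy")[:3]
    if rank < spec.n_basis:
        return None
    return coef


def evaluate_harmonic(
    coefficients: Sequence[float], spec: HarmonicBasisSpec, t
) -> np.ndarray:
    """Evaluate the fitted harmonic at time(s) ``t``."""
    coef = np.asarray(coefficients, dtype=float).ravel()
    if coef.size != spec.n_basis:
        raise ValueError(
            f"expected {spec.n_basis} coefficients for n={spec.n}, got {coef.size}"
        )
    t_arr = np.asarray(t, dtype=float)
    out = design_matrix(np.atleast_1d(t_arr), spec) @ coef
    return float(out[0]) if t_arr.ndim == 0 else out


def feature_names(spec: HarmonicBasisSpec = HarmonicBasisSpec()) -> Tuple[str, ...]:
    """Names of the stacked feature vector, band-major."""
    return tuple(
        f"{band}_{cname}" for band in FEATURE_BANDS for cname in spec.coefficient_names()
    )


def extract_features(
    stack: SceneStack, spec: HarmonicBasisSpec = HarmonicBasisSpec()
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-pixel harmonic features over NIR, SWIR1, SWIR2, and GCVI.

    Returns ``(features, insufficient)`` where ``features`` has shape
    (H, W, 4 * (2n+1)) and ``insufficient`` is a boolean (H, W) raster.
    A pixel is flagged insufficient when *any* of the four series cannot be
    fitted; its feature row is zeroed and must not be classified
    (such pixels later receive the unclassified code 0).

    Only valid observations enter the fits; GCVI additionally drops
    observations with green <= 0.
    """
    for band in ("Green", "NIR", "SWIR1", "SWIR2"):
        if band not in stack.bands:
            raise ValueError(f"stack is missing required band {band!r}")
    h, w = stack.shape
    p = spec.n_basis
    feats = np.zeros((h, w, 4 * p), dtype=float)
    insufficient = np.zeros((h, w), dtype=bool)

    bi = {b: stack.band_index(b) for b in ("Green", "NIR", "SWIR1", "SWIR2")}
    times = stack.times
    # cache design matrices by validity pattern (identical across many pixels
    # when cloud losses are low or absent)
    design_cache: Dict[bytes, np.ndarray] = {}

    for r in range(h):
        valid_r = stack.valid[:, r, :]
        for c in range(w):
            ok = valid_r[:, c]
            n_ok = int(ok.sum())
            if n_ok < p:
                insufficient[r, c] = True
                continue
            key = ok.tobytes()
            x = design_cache.get(key)
            if x is None:
                x = design_matrix(times[ok], spec)
                design_cache[key] = x
            nir = stack.values[ok, bi["NIR"], r, c]
            green = stack.values[ok, bi["Green"], r, c]
            rhs = np.column_stack(
                [
                    nir,
                    stack.values[ok, bi["SWIR1"], r, c],
                    stack.values[ok, bi["SWIR2"], r, c],
                ]
            )
            coef, _, rank = scipy.linalg.lstsq(x, rhs, lapack_driver="gelsy")[:3]
            g = gcvi(nir, green)
            g_ok = np.isfinite(g)
            if g_ok.all():
                gc, _, grank = scipy.linalg.lstsq(x, g, lapack_driver="gelsy")[:3]
            else:
                res = fit_harmonic(times[ok][g_ok], g[g_ok], spec)
                gc, grank = (res, p) if res is not None else (None, 0)
            if rank < p or grank < p or gc is None:
                insufficient[r, c] = True
                continue
            feats[r, c, 0:p] = coef[:, 0]
            feats[r, c, p : 2 * p] = coef[:, 1]
            feats[r, c, 2 * p : 3 * p] = coef[:, 2]
            feats[r, c, 3 * p : 4 * p] = gc
    return feats, insufficient


# ---------------------------------------------------------------------------
# Candidate-feature registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegistryEntry:
    """One candidate feature group considered during feature selection."""

    source: str
    name: str
    details: str
    n_features: int
    in_final_map: bool


@dataclass(frozen=True)
class FeatureRegistry:
    """Static catalogue of every feature group considered for the map."""

    entries: Tuple[RegistryEntry, ...]

    def total_feature_count(self) -> int:
        return sum(e.n_features for e in self.entries)

    def final_map_entries(self) -> Tuple[RegistryEntry, ...]:
        return tuple(e for e in self.entries if e.in_final_map)

    def final_map_feature_count(self) -> int:
        return sum(e.n_features for e in self.final_map_entries())


_REGISTRY = FeatureRegistry(
    entries=(
        RegistryEntry("Landsat", "Blue", "Harmonic coefficients", 5, False),
        RegistryEntry("Landsat", "Green", "Harmonic coefficients", 5, False),
        RegistryEntry("Landsat", "Red", "Harmonic coefficients", 5, False),
        RegistryEntry("Landsat", "NIR", "Harmonic coefficients", 5, True),
        RegistryEntry("Landsat", "SWIR1", "Harmonic coefficients", 5, True),
        RegistryEntry("Landsat", "SWIR2", "Harmonic coefficients", 5, True),
        RegistryEntry("Landsat", "GCVI", "Harmonic coefficients", 5, True),
        RegistryEntry("gridMET", "GDD", "Jan 1-Aug 31", 1, False),
        RegistryEntry("gridMET", "Mean monthly VPD", "Jun, Jul", 2, False),
        RegistryEntry("gridMET", "Mean monthly precip", "Jun, Jul, Aug", 3, False),
        RegistryEntry("gridMET", "Growing season precip", "May 1-Sep 15", 1, False),
        RegistryEntry("gridMET", "Early season precip", "Jan 1-Apr 30", 1, False),
        RegistryEntry(
            "gridMET", "Mean monthly max temp", "May, Jun, Jul, Aug", 4, False
        ),
        RegistryEntry(
            "gridMET", "Mean monthly min temp", "May, Jun, Jul, Aug", 4, False
        ),
        RegistryEntry("gridMET", "Aridity", "Jun 1-Aug 31", 1, False),
        RegistryEntry("TerraClimate", "Climate water deficit", "May, Jul", 2, False),
        RegistryEntry("TerraClimate", "Soil moisture", "Aug", 1, False),
    )
)


def registry() -> FeatureRegistry:
    """The candidate-feature catalogue (55 features; 20 in the final map).

    Weather covariates are catalogued only — they did not improve
    classification and are never computed by this pipeline.
    """
    return _REGISTRY
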