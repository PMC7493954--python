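"""Harmonic regression: basis, fitting, insufficiency rules, registry."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cornsoy.features import (
    FEATURE_BANDS,
    HarmonicBasisSpec,
    design_matrix,
    evaluate_harmonic,
    extract_features,
    feature_names,
    fit_harmonic,
    gcvi,
    registry,
)
from cornsoy.synth import (
    BANDS,
    CORN,
    AcquisitionSchedule,
    SceneLayout,
    default_phenologies,
    simulate_scene,
)

SPEC = HarmonicBasisSpec()
RNG = np.random.default_rng(2024)


# -- GCVI -------------------------------------------------------------------

def test_gcvi_is_nir_over_green_minus_one():
    assert gcvi(0.4, 0.4) == pytest.approx(0.0)
    assert gcvi(0.5, 0.25) == pytest.approx(1.0)
    nir = RNG.uniform(0.05, 0.6, 200)
    green = RNG.uniform(0.01, 0.3, 200)
    np.testing.assert_allclose(gcvi(nir, green), nir / green - 1.0, rtol=1e-15)


def test_gcvi_marks_nonpositive_green_invalid_not_raising():
    out = gcvi(np.array([0.3, 0.3]), np.array([0.0, -0.1]))
    assert np.isnan(out).all()
    assert np.isnan(gcvi(0.3, 0.0))


# -- design matrix ----------------------------------------------------------

def test_design_matrix_has_five_columns_for_second_order():
    assert design_matrix(np.linspace(0, 1, 7), SPEC).shape == (7, 5)


def test_design_matrix_row_at_time_zero():
    np.testing.assert_allclose(design_matrix(np.array([0.0]), SPEC)[0], [1, 1, 0, 1, 0])


def test_design_matrix_matches_scalar_trig_evaluation():
    t = RNG.uniform(0, 1, 13)
    spec = HarmonicBasisSpec(n=3, omega=0.8)
    x = design_matrix(t, spec)
    for i, ti in enumerate(t):
        row = [1.0]
        for k in range(1, 4):
            row += [np.cos(2 * np.pi * k * 0.8 * ti), np.sin(2 * np.pi * k * 0.8 * ti)]
        np.testing.assert_allclose(x[i], row, atol=1e-15)


# -- fitting ----------------------------------------------------------------

def test_constant_series_recovers_intercept_only():
    t = np.linspace(0.05, 0.95, 6)
    coef = fit_harmonic(t, np.full(6, 0.3), SPEC)
    np.testing.assert_allclose(coef, [0.3, 0, 0, 0, 0], atol=1e-12)


def test_noiseless_round_trip_recovers_coefficients():
    truth = RNG.normal(size=5)
    t = np.sort(RNG.uniform(0, 1, 10))
    v = evaluate_harmonic(truth, SPEC, t)
    np.testing.assert_allclose(fit_harmonic(t, v, SPEC), truth, atol=1e-8)


def test_fewer_than_five_points_is_insufficient():
    t = np.array([0.1, 0.3, 0.5, 0.7])
    assert fit_harmonic(t, np.ones(4), SPEC) is None


def test_duplicate_timestamps_only_is_insufficient_not_a_crash():
    t = np.full(8, 0.4)
    assert fit_harmonic(t, RNG.normal(size=8), SPEC) is None


def test_fit_ignores_non_finite_observations():
    truth = RNG.normal(size=5)
    t = np.sort(RNG.uniform(0, 1, 12))
    v = evaluate_harmonic(truth, SPEC, t)
    t_bad = np.concatenate([t, [0.2, 0.8]])
    v_bad = np.concatenate([v, [np.nan, np.inf]])
    np.testing.assert_array_equal(fit_harmonic(t_bad, v_bad, SPEC), fit_harmonic(t, v, SPEC))


@given(st.integers(0, 2**31 - 1))
def test_fit_invariant_to_observation_order(seed):
    rng = np.random.default_rng(seed)
    t = rng.uniform(0, 1, 9)
    v = rng.normal(size=9)
    perm = rng.permutation(9)
    a = fit_harmonic(t, v, SPEC)
    b = fit_harmonic(t[perm], v[perm], SPEC)
    np.testing.assert_array_equal(a, b)


def test_least_squares_optimality_under_coefficient_perturbation():
    t = np.sort(RNG.uniform(0, 1, 20))
    v = RNG.normal(0.3, 0.1, 20)
    coef = fit_harmonic(t, v, SPEC)
    x = design_matrix(t, SPEC)
    rss = ((v - x @ coef) ** 2).sum()
    for j in range(5):
        for eps in (1e-3, -1e-3):
            bumped = coef.copy()
            bumped[j] += eps
            assert ((v - x @ bumped) ** 2).sum() >= rss


def test_exact_interpolation_with_minimum_points():
    # 2n+1 distinct timestamps, full-rank design: residuals vanish
    t = np.array([0.05, 0.25, 0.45, 0.65, 0.85])
    v = RNG.normal(size=5)
    coef = fit_harmonic(t, v, SPEC)
    assert coef is not None
    np.testing.assert_allclose(evaluate_harmonic(coef, SPEC, t), v, atol=1e-8)


def test_evaluate_harmonic_edge_cases():
    assert evaluate_harmonic(np.zeros(5), SPEC, 0.37) == pytest.approx(0.0)
    assert evaluate_harmonic([1, 0, 0, 0, 0], SPEC, 0.9) == pytest.approx(1.0)
    coef = RNG.normal(size=5)
    t = RNG.uniform(0, 1, 6)
    manual = coef[0] + sum(
        coef[2 * k - 1] * np.cos(2 * np.pi * k * 1.5 * t)
        + coef[2 * k] * np.sin(2 * np.pi * k * 1.5 * t)
        for k in (1, 2)
    )
    np.testing.assert_allclose(evaluate_harmonic(coef, SPEC, t), manual, atol=1e-12)
    with pytest.raises(ValueError, match="coefficients"):
        evaluate_harmonic([1, 2, 3], SPEC, 0.5)


# -- raster extraction ------------------------------------------------------

def _tiny_scene(cloud_prob=0.2, seed=0):
    layout = SceneLayout(width=5, height=4, mixture={1: 0.4, 5: 0.4, 9: 0.2})
    return simulate_scene(
        default_phenologies(), AcquisitionSchedule(cloud_prob=cloud_prob), layout, seed
    )


def test_extract_matches_per_series_fits_and_has_twenty_features():
    stack, _, _ = _tiny_scene()
    feats, insufficient = extract_features(stack, SPEC)
    assert feats.shape == (4, 5, 20)
    assert not insufficient.any()
    r, c = 2, 3
    for bi, band in enumerate(FEATURE_BANDS):
        if band == "GCVI":
            t, nir = stack.series(r, c, "NIR")
            _, green = stack.series(r, c, "Green")
            v = gcvi(nir, green)
        else:
            t, v = stack.series(r, c, band)
        np.testing.assert_allclose(
            feats[r, c, 5 * bi : 5 * bi + 5], fit_harmonic(t, v, SPEC), atol=1e-10
        )


def test_all_invalid_pixel_is_flagged_insufficient():
    stack, _, _ = _tiny_scene(cloud_prob=0.0)
    stack.valid[:, 1, 2] = False
    feats, insufficient = extract_features(stack, SPEC)
    assert insufficient[1, 2]
    assert np.all(feats[1, 2] == 0.0)
    assert insufficient.sum() == 1


def test_corrupted_invalid_observations_never_change_features():
    stack, _, _ = _tiny_scene(cloud_prob=0.3, seed=3)
    base, _ = extract_features(stack, SPEC)
    stack.values[~np.broadcast_to(stack.valid[:, None], stack.values.shape)] = 99.0
    corrupted, _ = extract_features(stack, SPEC)
    np.testing.assert_array_equal(base, corrupted)


def test_missing_required_band_is_named():
    stack, _, _ = _tiny_scene()
    stack.bands = tuple(b for b in stack.bands if b != "SWIR1")
    stack.values = stack.values[:, [0, 1, 2, 3, 5]]
    with pytest.raises(ValueError, match="SWIR1"):
        extract_features(stack, SPEC)


# -- registry ---------------------------------------------------------------

def test_registry_counts_and_final_map_subset():
    reg = registry()
    assert reg.total_feature_count() == 55
    assert reg.final_map_feature_count() == 20
    finals = reg.final_map_entries()
    assert {e.name for e in finals} == {"NIR", "SWIR1", "SWIR2", "GCVI"}
    assert all(e.n_features == 5 for e in reg.entries if e.source == "Landsat")
    assert all(
        not e.in_final_map for e in reg.entries if e.source in ("gridMET", "TerraClimate")
    )
    assert len(feature_names(SPEC)) == 20
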