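"""Scene simulator: phenology ordering, reproducibility, masks, stress modes."""

import dataclasses

import numpy as np
import pytest

from cornsoy.features import gcvi
from cornsoy.synth import (
    BANDS,
    CORN,
    NONCROP,
    OTHER,
    SOYBEAN,
    AcquisitionSchedule,
    LabelRaster,
    SceneConfig,
    SceneLayout,
    default_phenologies,
    draw_classes,
    make_cropland_mask,
    median_valid_count,
    phenology_curve,
    scene_from_classes,
    simulate_scene,
    stress_scenario,
)

T_GRID = np.linspace(0.0, 1.0, 1000, endpoint=False)


def test_zero_amplitude_curve_is_base_reflectance():
    p = default_phenologies()[CORN]
    flat = dataclasses.replace(p, amplitude={b: 0.0 for b in BANDS})
    assert phenology_curve(flat, "NIR", p.peak_day) == flat.base_reflectance["NIR"]
    assert np.all(phenology_curve(flat, "NIR", T_GRID) == flat.base_reflectance["NIR"])


def test_unknown_band_raises_naming_it():
    with pytest.raises(ValueError, match="Magenta"):
        phenology_curve(default_phenologies()[CORN], "Magenta", 0.5)


@pytest.mark.parametrize("class_id", [CORN, SOYBEAN, OTHER, NONCROP])
def test_curve_maximal_at_peak_day(class_id):
    # brute-force grid maximization over 1000 times, for a positive-amplitude band
    p = default_phenologies()[class_id]
    at_peak = phenology_curve(p, "NIR", p.peak_day)
    assert np.all(at_peak >= phenology_curve(p, "NIR", T_GRID))


def test_soybean_peaks_later_and_higher_in_gcvi_than_corn():
    phen = default_phenologies()
    curves = {}
    for cls in (CORN, SOYBEAN):
        nir = phenology_curve(phen[cls], "NIR", T_GRID)
        green = phenology_curve(phen[cls], "Green", T_GRID)
        curves[cls] = gcvi(nir, green)
    assert T_GRID[np.argmax(curves[CORN])] < T_GRID[np.argmax(curves[SOYBEAN])]
    assert curves[SOYBEAN].max() > curves[CORN].max()
    # the configured peak GCVI is realized on the grid to curve resolution
    assert curves[CORN].max() == pytest.approx(phen[CORN].peak_gcvi, abs=1e-3)


def test_default_parameter_invariants():
    phen = default_phenologies()
    assert phen[SOYBEAN].peak_day > phen[CORN].peak_day
    assert phen[SOYBEAN].peak_gcvi > phen[CORN].peak_gcvi
    for p in phen.values():
        assert 0 <= p.peak_day < 1 and p.season_width > 0
        assert all(0 < p.base_reflectance[b] < 1 for b in BANDS)


def _small_layout(**kw):
    defaults = dict(width=12, height=12, mixture={CORN: 0.5, SOYBEAN: 0.5})
    defaults.update(kw)
    return SceneLayout(**defaults)


def test_no_clouds_means_every_observation_valid():
    sched = AcquisitionSchedule(cloud_prob=0.0)
    stack, _, _ = simulate_scene(default_phenologies(), sched, _small_layout(), seed=0)
    assert stack.valid.all()


def test_full_year_blackout_voids_every_observation():
    sched = AcquisitionSchedule(cloud_prob=0.0, blackout_windows=((0.0, 1.0),))
    stack, _, _ = simulate_scene(default_phenologies(), sched, _small_layout(), seed=0)
    assert not stack.valid.any()


def test_pure_corn_mixture_gives_all_corn_labels():
    layout = _small_layout(mixture={CORN: 1.0})
    _, labels, _ = simulate_scene(
        default_phenologies(), AcquisitionSchedule(), layout, seed=0
    )
    assert np.all(labels.data == CORN)


def test_empty_schedule_rejected():
    with pytest.raises(ValueError):
        AcquisitionSchedule(revisit_days=0.0)
    with pytest.raises(ValueError, match="no observation"):
        classes = draw_classes(_small_layout(), 0)
        sched = AcquisitionSchedule(revisit_days=400.0)
        assert sched.times().size <= 1  # sanity on the construction
        scene_from_classes(
            classes,
            default_phenologies(),
            dataclasses.replace(sched, revisit_days=1e9),
            0,
        )


def test_identical_seeds_give_bit_identical_scenes():
    args = (default_phenologies(), AcquisitionSchedule(), _small_layout())
    s1, l1, _ = simulate_scene(*args, seed=42)
    s2, l2, _ = simulate_scene(*args, seed=42)
    np.testing.assert_array_equal(s1.values, s2.values)
    np.testing.assert_array_equal(s1.valid, s2.valid)
    np.testing.assert_array_equal(l1.data, l2.data)
    s3, _, _ = simulate_scene(*args, seed=43)
    assert not np.array_equal(s1.values, s3.values)


def test_class_mixture_recovered_within_three_binomial_se():
    mixture = {CORN: 0.35, SOYBEAN: 0.30, OTHER: 0.20, NONCROP: 0.15}
    layout = SceneLayout(width=320, height=320, mixture=mixture)
    classes = draw_classes(layout, seed=11)
    n = classes.size
    for cls, p in mixture.items():
        freq = (classes == cls).mean()
        se = np.sqrt(p * (1 - p) / n)
        assert abs(freq - p) <= 3 * se


def test_noise_free_gcvi_series_separate_corn_from_soy_at_every_pixel():
    phen = {
        k: dataclasses.replace(p, noise_sd={b: 0.0 for b in BANDS})
        for k, p in default_phenologies().items()
    }
    layout = _small_layout(width=16, height=16)
    stack, labels, _ = simulate_scene(phen, AcquisitionSchedule(cloud_prob=0.3), layout, 5)
    gi, gr = stack.band_index("NIR"), stack.band_index("Green")
    maxima = {CORN: [], SOYBEAN: []}
    for r in range(16):
        for c in range(16):
            ok = stack.valid[:, r, c]
            g = gcvi(stack.values[ok, gi, r, c], stack.values[ok, gr, r, c])
            maxima[int(labels.data[r, c])].append(g.max())
    assert min(maxima[SOYBEAN]) > max(maxima[CORN])


# -- cropland masks ---------------------------------------------------------

def test_mask_without_flips_is_label_not_noncrop():
    labels = LabelRaster(
        data=np.array([[CORN, NONCROP], [SOYBEAN, OTHER]], dtype=np.uint8),
        pixel_area=900.0,
    )
    np.testing.assert_array_equal(
        make_cropland_mask(labels, 0.0, 0), labels.data != NONCROP
    )


def test_mask_flip_rate_realized_within_binomial_bound():
    rng = np.random.default_rng(0)
    data = rng.choice([CORN, SOYBEAN, OTHER, NONCROP], size=(100, 100)).astype(np.uint8)
    labels = LabelRaster(data=data, pixel_area=900.0)
    mask = make_cropland_mask(labels, 0.1, seed=1)
    disagreement = (mask != (data != NONCROP)).mean()
    assert 0.08 <= disagreement <= 0.12


def test_all_noncrop_label_yields_all_false_mask():
    labels = LabelRaster(
        data=np.full((4, 4), NONCROP, dtype=np.uint8), pixel_area=900.0
    )
    assert not make_cropland_mask(labels, 0.0, 0).any()


def test_mask_flip_rate_precondition():
    labels = LabelRaster(data=np.full((2, 2), CORN, dtype=np.uint8), pixel_area=1.0)
    with pytest.raises(ValueError):
        make_cropland_mask(labels, 0.5, 0)


# -- stress scenarios -------------------------------------------------------

def test_blackout_window_covers_both_crop_peaks():
    base = SceneConfig()
    stressed = stress_scenario("midseason_blackout", base)
    lo, hi = stressed.schedule.blackout_windows[-1]
    for cls in (CORN, SOYBEAN):
        assert lo <= base.phenologies[cls].peak_day < hi


def test_delayed_planting_narrows_corn_soy_peak_gap():
    base = SceneConfig()
    stressed = stress_scenario("delayed_planting", base)
    gap = lambda c: abs(c.phenologies[CORN].peak_day - c.phenologies[SOYBEAN].peak_day)
    assert gap(stressed) < gap(base)


def test_low_revisit_median_peak_season_count_at_most_four():
    base = SceneConfig(layout=_small_layout(width=10, height=10))
    stressed = stress_scenario("low_revisit", base)
    classes = draw_classes(stressed.layout, 3)
    stack = scene_from_classes(classes, stressed.phenologies, stressed.schedule, 3)
    assert median_valid_count(stack) <= 4.0


def test_unknown_scenario_error_lists_valid_names():
    with pytest.raises(ValueError, match="midseason_blackout"):
        stress_scenario("volcanic_winter", SceneConfig())
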