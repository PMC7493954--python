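"""Map validation statistics: confusion, accuracies, areas, R2, rotation, trends."""

import numpy as np
import pytest

from cornsoy.classify import CropMap
from cornsoy.metrics import (
    ACRE_M2,
    ConfusionMatrix,
    aggregate_area,
    area_trend,
    build_area_table,
    confusion,
    overall_accuracy,
    r_squared,
    rotation_fraction,
    squared_correlation,
    users_producers,
)
from cornsoy.synth import LabelRaster, RegionPartition


def _map(data, pixel_area=900.0, year=2018):
    return CropMap(data=np.asarray(data, dtype=np.uint8), year=year, pixel_area=pixel_area)


def _one_region(shape):
    return RegionPartition(region_ids=np.zeros(shape, dtype=np.int32), regions=(0,))


TOY_PRED = _map([[1, 1, 9]])
TOY_REF = _map([[1, 5, 9]])


def test_perfect_agreement_is_diagonal():
    cm = confusion(TOY_REF, TOY_REF)
    assert np.all(cm.counts == np.diag(np.diag(cm.counts)))
    assert overall_accuracy(cm) == 1.0
    for c in (1, 5, 9):
        assert users_producers(cm, c) == (1.0, 1.0)


def test_hand_enumerated_toy_confusion():
    cm = confusion(TOY_PRED, TOY_REF)
    assert cm.tp(1) == 1 and cm.fp(1) == 1 and cm.fn(5) == 1 and cm.tp(9) == 1
    assert overall_accuracy(cm) == pytest.approx(2 / 3)
    ua, pa = users_producers(cm, 1)
    assert ua == pytest.approx(1 / 2)
    assert pa == pytest.approx(1.0)


def test_users_accuracy_equals_brute_force_precision():
    rng = np.random.default_rng(3)
    pred = _map(rng.choice([1, 5, 9], size=(20, 20)))
    ref = _map(rng.choice([1, 5, 9], size=(20, 20)))
    cm = confusion(pred, ref)
    for c in (1, 5, 9):
        sel = pred.data == c
        precision = (ref.data[sel] == c).mean()
        recall = (pred.data[ref.data == c] == c).mean()
        ua, pa = users_producers(cm, c)
        assert ua == pytest.approx(precision)
        assert pa == pytest.approx(recall)


def test_noncrop_and_unclassified_excluded_symmetrically():
    cm_all = confusion(TOY_PRED, TOY_REF)
    pred = _map([[1, 1, 9, 255]])
    ref = _map([[1, 5, 9, 1]])
    cm = confusion(pred, ref)
    assert cm.total == cm_all.total  # the 255 pixel adds nothing
    assert cm.excluded == 1
    with pytest.raises(ValueError, match="geometry"):
        confusion(pred, TOY_REF)


def test_overall_accuracy_decomposes_over_classes():
    rng = np.random.default_rng(7)
    cm = confusion(
        _map(rng.choice([1, 5, 9, 0], (30, 30))), _map(rng.choice([1, 5, 9], (30, 30)))
    )
    oa = overall_accuracy(cm)
    assert oa == pytest.approx(sum(cm.tp(c) for c in (1, 5, 9)) / cm.total)
    # producer's accuracies weighted by reference frequencies sum to overall
    weighted = sum(
        users_producers(cm, c)[1] * (cm.tp(c) + cm.fn(c)) / cm.total for c in (1, 5, 9)
    )
    assert oa == pytest.approx(weighted)


def test_undefined_statistics_are_flagged_none():
    cm = ConfusionMatrix(counts=np.zeros((3, 3), dtype=int))
    assert overall_accuracy(cm) is None
    assert users_producers(cm, 1) == (None, None)
    with pytest.raises(ValueError, match="unknown class"):
        users_producers(cm, 2)


# -- areas ------------------------------------------------------------------

def test_aggregate_area_arithmetic_and_units():
    data = np.full((2, 5), 9, dtype=np.uint8)
    data[0, :] = 1  # 10 pixels total, 5 corn
    m = _map(np.tile(data, (5, 1))[:4], pixel_area=900.0)  # 4x5: 10 corn pixels
    part = _one_region(m.shape)
    assert aggregate_area(m, part, 1, "m2")[0] == pytest.approx(9000.0)
    assert aggregate_area(m, part, 1, "ha")[0] == pytest.approx(0.9)
    assert aggregate_area(m, part, 1, "acre")[0] == pytest.approx(9000.0 / ACRE_M2)
    with pytest.raises(ValueError, match="unit"):
        aggregate_area(m, part, 1, "furlong2")


def test_region_areas_sum_to_whole_map_aggregate():
    rng = np.random.default_rng(1)
    m = _map(rng.choice([1, 5, 9, 255], (8, 8)))
    ids = (np.arange(64).reshape(8, 8) // 16).astype(np.int32)
    part = RegionPartition(region_ids=ids, regions=(0, 1, 2, 3))
    per_region = aggregate_area(m, part, 5, "m2")
    whole = aggregate_area(m, _one_region(m.shape), 5, "m2")[0]
    assert sum(per_region.values()) == pytest.approx(whole)
    # per-region counts match a hand count
    for region in part.regions:
        expected = (m.data[part.mask(region)] == 5).sum() * 900.0
        assert per_region[region] == pytest.approx(expected)


# -- R2 and r2 --------------------------------------------------------------

def test_raw_value_r_squared_examples():
    y = np.array([1.0, 2.0, 3.0])
    assert r_squared(y, y) == pytest.approx(1.0)
    assert r_squared(y, np.full(3, y.mean())) == pytest.approx(0.0)
    assert r_squared(y, np.array([3.0, 2.0, 1.0])) == pytest.approx(-3.0)
    assert r_squared(np.array([2.0, 2.0]), np.array([1.0, 3.0])) is None


def test_r_squared_invariant_to_common_unit_rescaling():
    rng = np.random.default_rng(0)
    y = rng.uniform(10, 100, 20)
    yhat = y + rng.normal(0, 5, 20)
    assert r_squared(y, yhat) == pytest.approx(r_squared(y * 0.404686, yhat * 0.404686))


def test_squared_correlation_differs_from_raw_r2_under_bias():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    yhat = y + 10.0  # perfectly correlated, heavily biased
    assert squared_correlation(y, yhat) == pytest.approx(1.0)
    assert r_squared(y, yhat) < 0.0


# -- rotation ---------------------------------------------------------------

def test_rotation_fraction_trivial_and_toy_cases():
    part = _one_region((1, 4))
    all_soy = _map([[5, 5, 5, 5]], year=2000)
    all_corn = _map([[1, 1, 1, 1]], year=2001)
    assert rotation_fraction(all_soy, all_corn, part)[0].fraction == 1.0
    assert rotation_fraction(all_corn, all_corn, part)[0].fraction == 0.0
    prev = _map([[5, 5, 1, 9]], year=2000)
    curr = _map([[1, 1, 1, 1]], year=2001)
    rec = rotation_fraction(prev, curr, part)[0]
    assert rec.fraction == pytest.approx(2 / 3)  # the 9-prior pixel is excluded
    no_corn = _map([[5, 5, 5, 5]], year=2001)
    assert rotation_fraction(prev, no_corn, part)[0].fraction is None


# -- trends -----------------------------------------------------------------

def test_area_trend_slopes():
    years = [2000, 2001, 2002]
    assert area_trend(years, [7.0, 7.0, 7.0]) == pytest.approx(0.0)
    assert area_trend(years, years) == pytest.approx(1.0)
    assert area_trend(years, [10.0, 14.0, 18.0]) == pytest.approx(4.0)
    assert area_trend([2000], [10.0]) is None


def test_area_table_reference_matches_labels():
    labels = LabelRaster(
        data=np.array([[1, 5], [9, 255]], dtype=np.uint8), pixel_area=1e4
    )
    maps = {2018: _map([[1, 1], [9, 255]], pixel_area=1e4)}
    table = build_area_table(maps, {2018: labels}, _one_region((2, 2)), unit="ha")
    corn = table[table["class_code"] == 1].iloc[0]
    assert corn["predicted_area"] == pytest.approx(2.0)
    assert corn["reference_area"] == pytest.approx(1.0)
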