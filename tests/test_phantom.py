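"""Phantom generator: geometry, determinism, rater models, planted effects."""

import dataclasses

import numpy as np
import pytest

from atlasparc import (PhantomSpec, RaterModel, make_cohort, make_phantom,
                       multilabel_dice, plant_group_effect, simulate_raters)
from atlasparc.groupstats import cohort_volume_table
from atlasparc.phantom import corrupt_subject, diagonal_confusion


def test_noiseless_phantom_is_piecewise_constant():
    spec = PhantomSpec(shape=(24, 24, 24), n_structures_per_hemisphere=2,
                       noise_sd=0.0, bias_amplitude=0.0, seed=3)
    img, lab, mask = make_phantom(spec)
    for lid in [0] + lab.table.ids:
        vals = np.unique(img.data[lab.data == lid])
        assert len(vals) == 1, f"label {lid} not constant"


def test_phantom_determinism(small_spec):
    a = make_phantom(small_spec)
    b = make_phantom(small_spec)
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x.data, y.data)
    ca = make_cohort(small_spec, 3, deformation_sd=1.0, seed=5)
    cb = make_cohort(small_spec, 3, deformation_sd=1.0, seed=5)
    for sa, sb in zip(ca, cb):
        np.testing.assert_array_equal(sa.image.data, sb.image.data)
        np.testing.assert_array_equal(sa.labels.data, sb.labels.data)


def test_structure_count_64cubed():
    spec = PhantomSpec(shape=(64, 64, 64), n_structures_per_hemisphere=10,
                       seed=1)
    _, lab, _ = make_phantom(spec)
    assert len(np.unique(lab.data)) == 21  # 20 structures + background


def test_bilateral_label_mode():
    spec = PhantomSpec(shape=(32, 32, 32), n_structures_per_hemisphere=3,
                       bilateral_labels=True, asymmetry_jitter=0.0, seed=2)
    _, lab, _ = make_phantom(spec)
    assert lab.table.ids == [1, 2, 3]


def test_too_many_structures_raises():
    spec = PhantomSpec(shape=(16, 16, 16), n_structures_per_hemisphere=2000,
                       seed=0)
    with pytest.raises(ValueError, match="tile"):
        make_phantom(spec)


def test_cohort_sd0_identical_and_shared_table(small_spec):
    db = make_cohort(small_spec, 3, deformation_sd=0.0)
    base_img, base_lab, _ = make_phantom(small_spec)
    assert len(db) == 3
    for s in db:
        np.testing.assert_array_equal(s.image.data, base_img.data)
        np.testing.assert_array_equal(s.labels.data, base_lab.data)
        assert s.labels.table == db.table


def test_cohort_dice_decreases_with_deformation(small_spec):
    means = []
    for sd in (0.5, 1.0, 2.0):
        db = make_cohort(small_spec, 3, deformation_sd=sd, seed=9)
        pair_dice = []
        for i in range(len(db)):
            for j in range(i + 1, len(db)):
                pair_dice.append(multilabel_dice(db[i].labels, db[j].labels)[1])
        means.append(np.mean(pair_dice))
    assert means[0] > means[1] > means[2]


def test_label_conservation(small_cohort):
    ids = set(small_cohort.table.ids) | {0}
    for s in small_cohort:
        assert set(np.unique(s.labels.data)) <= ids


def test_identity_confusion_raters_equal_truth(small_phantom):
    _, lab, _ = small_phantom
    k = len(lab.table.ids) + 1
    raters = simulate_raters(lab, RaterModel(confusion=np.eye(k), seed=1), 3)
    for r in raters:
        np.testing.assert_array_equal(r.data, lab.data)


def test_zero_jitter_raters_equal_truth(small_phantom):
    _, lab, _ = small_phantom
    raters = simulate_raters(lab, RaterModel(jitter_sd=0.0, seed=1), 2)
    for r in raters:
        np.testing.assert_array_equal(r.data, lab.data)


def test_empirical_confusion_matches_model():
    """At 64^3, the tabulated observed-vs-true confusion of a simulated
    rater converges to the model matrix within +-0.02 per entry."""
    spec = PhantomSpec(shape=(64, 64, 64), n_structures_per_hemisphere=3,
                       seed=8)
    _, lab, _ = make_phantom(spec)
    ids = [0] + lab.table.ids
    k = len(ids)
    model = diagonal_confusion(k - 1, 0.9)
    raters = simulate_raters(lab, RaterModel(confusion=model, seed=4), 2)
    code = {lid: c for c, lid in enumerate(ids)}
    truth_codes = np.vectorize(code.get)(lab.data)
    for r in raters:
        obs_codes = np.vectorize(code.get)(r.data)
        emp = np.zeros((k, k))
        np.add.at(emp, (obs_codes.ravel(), truth_codes.ravel()), 1.0)
        emp /= np.maximum(emp.sum(axis=0, keepdims=True), 1)
        assert np.abs(emp - model).max() < 0.02


def test_confusion_matrix_validation():
    bad = np.array([[0.9, 0.2], [0.2, 0.8]])  # columns sum to 1.1 / 1.0
    with pytest.raises(ValueError, match="sum to 1"):
        RaterModel(confusion=bad)


def test_plant_scale_one_is_identity(small_cohort):
    groups = ["a", "a", "b", "b"]
    out = plant_group_effect(small_cohort, 1, 1.0, groups, "b")
    for s0, s1 in zip(small_cohort, out):
        np.testing.assert_array_equal(s0.labels.data, s1.labels.data)


def test_planted_effect_ratio_and_isolation(small_spec):
    db = make_cohort(small_spec, 6, deformation_sd=0.5, seed=13)
    groups = ["wt"] * 3 + ["tc"] * 3
    out = plant_group_effect(db, 2, 1.3, groups, "tc")
    assert 1.25 <= out.meta["achieved_ratio"] <= 1.35
    before = cohort_volume_table(db.replace(
        [dataclasses.replace(s, group=g) for s, g in zip(db, groups)]))
    after = cohort_volume_table(out)
    merged = before.merge(after, on=["subject", "structure"],
                          suffixes=("_0", "_1"))
    others = merged[merged.structure != 2]
    rel = (others.volume_mm3_1 / others.volume_mm3_0 - 1).abs()
    assert rel.max() < 0.02


def test_corrupt_subject_changes_only_locally(small_cohort):
    subj = small_cohort[1]
    out = corrupt_subject(subj, magnitude=3.0, seed=5)
    changed = out.labels.data != subj.labels.data
    assert 0 < changed.mean() < 0.5  # local, not global, corruption
    assert out.meta.get("corrupted")
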