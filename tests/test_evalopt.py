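"""LOOCV, the parameter sweep, method comparison and FDR correction."""

import dataclasses

import numpy as np
import pytest

from atlasparc import (IdentityBackend, PhantomSpec, StepsParams, default_sweep_grid,
                       fdr_bh, loocv, make_cohort, steps, sweep)
from atlasparc.evalopt import EVAL_CONFIG, SweepGrid, compare_methods
from atlasparc.pipeline import propagate

from conftest import bh_oracle


def test_default_grid_cardinality():
    grid = default_sweep_grid()
    assert len(grid.sigmas) == 11
    assert len(grid.top_x) == 7
    assert len(grid) == 77
    assert grid.sigmas[0] == 1.0 and grid.sigmas[-1] == 6.0
    assert grid.top_x == tuple(range(3, 10))


def test_grid_validation():
    with pytest.raises(ValueError):
        SweepGrid(sigmas=(), top_x=(3,))
    with pytest.raises(ValueError):
        SweepGrid(sigmas=(2.0, 1.0), top_x=(3,))


@pytest.fixture(scope="module")
def eval_cfg():
    return dataclasses.replace(
        EVAL_CONFIG, steps_params=StepsParams(sigma=2.0, top_x=2, beta=0.5))


def test_loocv_identical_cohort_is_perfect(identical_cohort, eval_cfg):
    records = loocv(identical_cohort, eval_cfg, IdentityBackend())
    assert (records["dice"] == 1.0).all()
    assert set(records["subject"]) == {s.subject_id for s in identical_cohort}


def test_loocv_topx_bound(identical_cohort):
    cfg = dataclasses.replace(
        EVAL_CONFIG, steps_params=StepsParams(top_x=4))  # |db|-1 == 3
    with pytest.raises(ValueError, match="top-X"):
        loocv(identical_cohort, cfg, IdentityBackend())


def test_loocv_degrades_with_deformation(small_spec, eval_cfg):
    means = []
    for sd in (0.5, 2.0):
        db = make_cohort(small_spec, 4, deformation_sd=sd, seed=41)
        rec = loocv(db, eval_cfg, IdentityBackend())
        means.append(rec.groupby("subject")["dice"].mean().mean())
    assert means[0] > means[1]


def test_loocv_no_leakage(small_spec, eval_cfg):
    """Corrupting the left-out subject's labels must not change the fused
    segmentation of its own fold."""
    db = make_cohort(small_spec, 4, deformation_sd=0.5, seed=43)
    target, rest = db.leave_out(0)
    be = IdentityBackend()
    imgs, labs = zip(*(propagate(a, target.image, be) for a in rest))
    fused_1 = steps(target.image, list(imgs), list(labs),
                    eval_cfg.steps_params, label_ids=db.table.ids)
    scrambled = target.labels.with_data(
        np.where(target.labels.data > 0, (target.labels.data % 6) + 1, 0))
    target_2 = dataclasses.replace(target, labels=scrambled)
    db_2 = db.replace([target_2] + list(rest.subjects))
    target_2b, rest_2 = db_2.leave_out(0)
    imgs2, labs2 = zip(*(propagate(a, target_2b.image, be) for a in rest_2))
    fused_2 = steps(target_2b.image, list(imgs2), list(labs2),
                    eval_cfg.steps_params, label_ids=db.table.ids)
    np.testing.assert_array_equal(fused_1.labels.data, fused_2.labels.data)


class TestSweep:
    def test_identical_cohort_all_cells_perfect_and_tie_rule(
            self, identical_cohort, eval_cfg):
        grid = SweepGrid(sigmas=(1.0, 2.0), top_x=(1, 2))
        res = sweep(identical_cohort, grid, eval_cfg, IdentityBackend())
        assert np.allclose(res.mean_dice.to_numpy(), 1.0)
        assert res.best_sigma == 1.0 and res.best_top_x == 1  # smallest X, sigma
        assert res.best_mean_dice >= res.mean_dice.to_numpy().max() - 1e-12

    def test_caching_matches_naive_recomputation(self, small_spec, eval_cfg):
        db = make_cohort(small_spec, 3, deformation_sd=0.8, seed=47)
        grid = SweepGrid(sigmas=(1.5, 3.0), top_x=(1, 2))
        res = sweep(db, grid, eval_cfg, IdentityBackend())
        be = IdentityBackend()
        for sigma in grid.sigmas:
            for x in grid.top_x:
                vals = []
                for i in range(len(db)):
                    target, rest = db.leave_out(i)
                    imgs, labs = zip(*(propagate(a, target.image, be)
                                       for a in rest))
                    params = dataclasses.replace(eval_cfg.steps_params,
                                                 sigma=sigma, top_x=x)
                    fused = steps(target.image, list(imgs), list(labs),
                                  params, label_ids=db.table.ids)
                    from atlasparc import multilabel_dice
                    vals.append(multilabel_dice(fused.labels,
                                                target.labels)[1])
                naive = float(np.mean(vals))
                assert res.mean_dice.loc[sigma, x] == pytest.approx(
                    naive, abs=1e-12)

    def test_topx_exceeding_cohort_rejected(self, identical_cohort, eval_cfg):
        grid = SweepGrid(sigmas=(2.0,), top_x=(4,))
        with pytest.raises(ValueError, match="top-X"):
            sweep(identical_cohort, grid, eval_cfg, IdentityBackend())


class TestCompareMethods:
    def test_identical_cohort_yields_no_discoveries(self, identical_cohort,
                                                    eval_cfg):
        res = compare_methods(identical_cohort, eval_cfg, IdentityBackend())
        assert not res.tests["significant"].any()
        assert res.tests["p"].isna().all()  # zero paired variance everywhere

    def test_method_means_structure(self, small_spec, eval_cfg):
        db = make_cohort(small_spec, 4, deformation_sd=0.8, seed=51)
        res = compare_methods(db, eval_cfg, IdentityBackend())
        means = res.method_means()
        assert set(means.index) == {"single", "staple", "steps"}
        assert set(res.tests["comparison"]) == {"steps_vs_single",
                                                "steps_vs_staple"}


class TestFdrBh:
    def test_worked_example(self):
        # sorted-threshold rule with m=4, q=0.05: thresholds
        # (0.0125, 0.025, 0.0375, 0.05); 0.04 > 0.0375 so k* = 2
        p = np.array([0.001, 0.01, 0.04, 0.2])
        flags = fdr_bh(p, q=0.05)
        np.testing.assert_array_equal(flags, bh_oracle(p, 0.05))
        np.testing.assert_array_equal(flags, [True, True, False, False])

    def test_matches_bruteforce_oracle_on_random_vectors(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            m = rng.integers(1, 60)
            p = rng.random(m) ** rng.uniform(0.3, 3.0)
            q = rng.uniform(0.01, 0.2)
            np.testing.assert_array_equal(fdr_bh(p, q), bh_oracle(p, q))

    def test_nans_never_rejected(self):
        flags = fdr_bh(np.array([0.001, np.nan, 0.002]), q=0.05)
        assert not flags[1] and flags[0] and flags[2]
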