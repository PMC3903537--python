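"""Label fusion: majority vote, STAPLE EM and STEPS selection behaviour."""

import numpy as np
import pytest

from atlasparc import (RaterModel, StepsParams, majority_vote, multilabel_dice,
                       rank_atlases, simulate_raters, staple, steps)
from atlasparc.imageio import LabelEntry, LabelMap, LabelTable
from atlasparc.phantom import diagonal_confusion


@pytest.fixture(scope="module")
def jitter_raters(small_phantom):
    _, lab, _ = small_phantom
    return simulate_raters(lab, RaterModel(jitter_sd=1.0, seed=6), 4)


class TestMajorityVote:
    def test_unanimity(self, small_phantom):
        _, lab, _ = small_phantom
        res = majority_vote([lab, lab, lab])
        np.testing.assert_array_equal(res.labels.data, lab.data)

    def test_vote_fraction_and_tie_rule(self):
        table = LabelTable({1: LabelEntry("a"), 2: LabelEntry("b")})
        base = np.zeros((16, 16, 16), int)
        base[8, 8, 8] = 1
        other = base.copy()
        other[8, 8, 8] = 2
        maps = [LabelMap(base, table), LabelMap(base, table),
                LabelMap(other, table)]
        res = majority_vote(maps)
        assert res.labels.data[8, 8, 8] == 1
        c1 = res.label_ids.index(1)
        assert res.posterior[c1, 8, 8, 8] == pytest.approx(2 / 3)
        # 1-1 tie goes to the smallest id
        tie = majority_vote([LabelMap(base, table), LabelMap(other, table)])
        assert tie.labels.data[8, 8, 8] == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])


class TestStaple:
    def test_perfect_raters_fixed_point(self, small_phantom):
        _, lab, _ = small_phantom
        res = staple([lab, lab, lab])
        np.testing.assert_array_equal(res.labels.data, lab.data)
        for th in res.confusion:
            assert np.abs(th - np.eye(th.shape[0])).max() < 1e-3

    def test_single_rater_degenerate(self, small_phantom):
        _, lab, _ = small_phantom
        res = staple([lab])
        np.testing.assert_array_equal(res.labels.data, lab.data)

    def test_confusion_recovery_and_beats_majority_vote(self, small_phantom):
        """Raters drawn from a known diag-0.9 confusion: EM recovers the
        diagonal within +-0.05 and the fusion is at least as accurate as
        majority voting."""
        _, lab, _ = small_phantom
        k = len(lab.table.ids)
        raters = simulate_raters(
            lab, RaterModel(confusion=diagonal_confusion(k, 0.9), seed=14), 6)
        res = staple(raters, label_ids=lab.table.ids)
        diag = np.diagonal(res.confusion, axis1=1, axis2=2)
        assert np.abs(diag - 0.9).max() < 0.05
        _, d_staple = multilabel_dice(res.labels, lab)
        _, d_mv = multilabel_dice(majority_vote(raters).labels, lab)
        assert d_staple >= d_mv - 1e-6

    def test_log_likelihood_monotone(self, jitter_raters):
        res = staple(jitter_raters)
        ll = np.asarray(res.log_likelihood)
        assert res.iterations >= 3
        assert np.all(np.diff(ll) >= -1e-6 * np.abs(ll[:-1]))

    def test_permutation_equivariance(self, jitter_raters):
        res = staple(jitter_raters)
        perm = [2, 0, 3, 1]
        res_p = staple([jitter_raters[i] for i in perm])
        np.testing.assert_array_equal(res.labels.data, res_p.labels.data)
        np.testing.assert_allclose(res.posterior, res_p.posterior, atol=1e-12)
        np.testing.assert_allclose(res.confusion[perm], res_p.confusion,
                                   atol=1e-12)

    def test_posterior_normalised_and_label_closure(self, jitter_raters,
                                                    small_phantom):
        _, lab, _ = small_phantom
        res = staple(jitter_raters)
        sums = res.posterior.sum(axis=0)
        assert np.abs(sums[res.roi] - 1.0).max() < 1e-6
        input_ids = set()
        for r in jitter_raters:
            input_ids |= set(r.present_ids())
        assert set(np.unique(res.labels.data)) - {0} <= input_ids

    def test_unknown_label_rejected(self, small_phantom):
        _, lab, _ = small_phantom
        with pytest.raises(ValueError, match="outside"):
            staple([lab], label_ids=[1])


class TestRanking:
    def test_perfect_atlas_ranks_first(self, small_phantom):
        img, lab, _ = small_phantom
        rng = np.random.default_rng(0)
        noise = img.with_data(rng.random(img.shape).astype(np.float32) * 100)
        rank = rank_atlases(img, [noise, img], sigma=2.0)
        roi = lab.data > 0
        assert (rank.ranks[1][roi] == 0).mean() >= 0.99

    def test_tie_resolved_by_input_order(self, small_phantom):
        img, _, _ = small_phantom
        rank = rank_atlases(img, [img, img], sigma=2.0)
        assert np.all(rank.ranks[0] == 0) and np.all(rank.ranks[1] == 1)

    def test_full_selection(self, small_phantom):
        img, _, _ = small_phantom
        rank = rank_atlases(img, [img, img, img], sigma=2.0)
        assert rank.selection(3).all()


class TestSteps:
    def test_degenerate_limit_matches_staple(self, small_phantom,
                                             jitter_raters):
        img, _, _ = small_phantom
        n = len(jitter_raters)
        params = StepsParams(sigma=2 * max(img.shape), top_x=n, beta=0.0)
        res_steps = steps(img, [img] * n, jitter_raters, params)
        res_staple = staple(jitter_raters)
        agree = (res_steps.labels.data == res_staple.labels.data)[res_steps.roi]
        assert agree.mean() >= 0.99

    def test_top1_follows_identical_atlas(self, small_phantom):
        img, lab, _ = small_phantom
        rng = np.random.default_rng(3)
        noise = img.with_data(rng.random(img.shape).astype(np.float32) * 100)
        wrong = lab.with_data(np.where(lab.data > 0, (lab.data % 6) + 1, 0))
        res = steps(img, [img, noise], [lab, wrong],
                    StepsParams(sigma=2.0, top_x=1, beta=0.0))
        agree = (res.labels.data == lab.data)[res.roi]
        assert agree.mean() >= 0.99

    def test_topx_bound(self, small_phantom, jitter_raters):
        img, _, _ = small_phantom
        with pytest.raises(ValueError, match="top-X"):
            steps(img, [img] * 4, jitter_raters, StepsParams(top_x=5))

    def test_mrf_smooths_but_preserves_most_voxels(self, small_phantom,
                                                   jitter_raters):
        img, _, _ = small_phantom
        on = steps(img, [img] * 4, jitter_raters,
                   StepsParams(sigma=2.0, top_x=2, beta=0.5))
        off = steps(img, [img] * 4, jitter_raters,
                    StepsParams(sigma=2.0, top_x=2, beta=0.0))
        changed = (on.labels.data != off.labels.data)[on.roi].mean()
        assert changed <= 0.05
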