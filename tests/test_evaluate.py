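"""Confusion metrics, pixel AUC vs the rank-statistic oracle, FROC, CV summary."""

import numpy as np
import pytest

from dbtseg.config import EvaluationGroup, PostprocessGroup
from dbtseg.evaluate import (
    ConfusionCounts,
    acc_sen_spe,
    confusion,
    crossval_report,
    dice_coefficient,
    froc,
    match_lesions,
    roc_auc,
)
from dbtseg.volume import Heatmap, MaskVolume


def rank_auc_oracle(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney formulation: P(s+ > s-) + 0.5 P(s+ = s-)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


def _mask(arr, ids=None):
    return MaskVolume(np.asarray(arr, dtype=np.uint8), ids)


class TestConfusion:
    def test_perfect_prediction(self):
        rng = np.random.default_rng(0)
        t = (rng.random((2, 8, 8)) > 0.5).astype(np.uint8)
        c = confusion(_mask(t), _mask(t))
        assert c.FP == 0 and c.FN == 0
        assert c.TP + c.TN == t.size

    def test_inverted_prediction(self):
        t = np.zeros((1, 4, 4), dtype=np.uint8)
        t[0, :2] = 1
        c = confusion(_mask(1 - t), _mask(t))
        assert c.TP == 0 and c.TN == 0

    def test_hand_counted_toy_slice(self):
        truth = np.zeros((1, 4, 4), dtype=np.uint8)
        pred = np.zeros((1, 4, 4), dtype=np.uint8)
        truth[0, 1, 1] = truth[0, 1, 2] = truth[0, 2, 1] = 1   # 3 true voxels
        pred[0, 1, 1] = pred[0, 1, 2] = 1                       # 2 hits, misses (2,1)
        pred[0, 3, 3] = 1                                       # 1 spurious
        c = confusion(_mask(pred), _mask(truth))
        assert (c.TP, c.FN, c.FP, c.TN) == (2, 1, 1, 12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            confusion(_mask(np.zeros((1, 4, 4))), _mask(np.zeros((1, 5, 5))))


class TestAccSenSpe:
    def test_worked_example(self):
        acc, sen, spe = acc_sen_spe(ConfusionCounts(TP=8, FP=5, TN=85, FN=2))
        assert acc == pytest.approx(0.93)
        assert sen == pytest.approx(0.80)
        assert spe == pytest.approx(85 / 90)

    def test_perfect(self):
        assert acc_sen_spe(ConfusionCounts(10, 0, 90, 0)) == (1.0, 1.0, 1.0)

    def test_undefined_sensitivity(self):
        with pytest.raises(ZeroDivisionError, match="SEN"):
            acc_sen_spe(ConfusionCounts(TP=0, FP=3, TN=7, FN=0))

    def test_recovers_rates_on_large_draws(self):
        rng = np.random.default_rng(1)
        n = 200_000
        truth = rng.random(n) < 0.3
        sen_true, spe_true = 0.85, 0.9
        pred = np.where(truth, rng.random(n) < sen_true, rng.random(n) > spe_true)
        c = ConfusionCounts(
            TP=int((pred & truth).sum()),
            FP=int((pred & ~truth).sum()),
            TN=int((~pred & ~truth).sum()),
            FN=int((~pred & truth).sum()),
        )
        _, sen, spe = acc_sen_spe(c)
        assert sen == pytest.approx(sen_true, abs=0.01)
        assert spe == pytest.approx(spe_true, abs=0.01)


class TestRocAuc:
    def test_heatmap_equal_truth_is_one(self):
        t = np.zeros((1, 6, 6), dtype=np.uint8)
        t[0, :3] = 1
        assert roc_auc(Heatmap(t.astype(float)), _mask(t)) == pytest.approx(1.0)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(2)
        t = (rng.random((4, 20, 20)) > 0.5).astype(np.uint8)
        s = rng.random(t.shape)
        assert roc_auc(Heatmap(s), _mask(t)) == pytest.approx(0.5, abs=0.03)

    def test_score_reversal_symmetry(self):
        rng = np.random.default_rng(3)
        t = (rng.random((2, 10, 10)) > 0.7).astype(np.uint8)
        s = rng.random(t.shape)
        a = roc_auc(Heatmap(s), _mask(t))
        b = roc_auc(Heatmap(1 - s), _mask(t))
        assert a == pytest.approx(1 - b, abs=1e-12)

    def test_trapezoid_equals_rank_statistic_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            t = (rng.random((1, 8, 8)) > 0.6).astype(np.uint8)
            if t.min() == t.max():
                continue
            # quantized scores force ties through both code paths
            s = np.round(rng.random(t.shape), 1)
            got = roc_auc(Heatmap(s), _mask(t))
            want = rank_auc_oracle(s.ravel(), t.ravel())
            assert got == pytest.approx(want, abs=1e-9)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(Heatmap(np.zeros((1, 4, 4))), _mask(np.zeros((1, 4, 4))))


class TestLesionMatching:
    def _truth_with_two_lesions(self):
        labels = np.zeros((4, 32, 32), dtype=np.uint8)
        ids = np.zeros_like(labels, dtype=np.int32)
        labels[1, 5:10, 5:10] = 1
        ids[1, 5:10, 5:10] = 1
        labels[2, 20:26, 20:26] = 1
        ids[2, 20:26, 20:26] = 2
        return _mask(labels, ids)

    def test_hit_one_miss_one_with_spurious(self):
        truth = self._truth_with_two_lesions()
        pred = np.zeros((4, 32, 32), dtype=np.uint8)
        pred[1, 6:9, 6:9] = 1      # overlaps lesion 1
        pred[0, 28:31, 0:3] = 1    # spurious component
        hits, total, fp = match_lesions(_mask(pred), truth)
        assert (hits, total, fp) == (1, 2, 1)

    def test_missing_lesion_ids_rejected(self):
        truth = _mask(np.zeros((1, 8, 8)))
        with pytest.raises(ValueError, match="lesion"):
            match_lesions(_mask(np.zeros((1, 8, 8))), truth)


class TestFroc:
    def _volumes(self):
        truths, heatmaps = [], []
        # volume A: 2 lesions, both predicted confidently + 2 spurious blobs
        labels = np.zeros((4, 48, 48), dtype=np.uint8)
        ids = np.zeros_like(labels, dtype=np.int32)
        labels[0:2, 4:12, 4:12] = 1
        ids[0:2, 4:12, 4:12] = 1
        labels[2:4, 30:40, 30:40] = 1
        ids[2:4, 30:40, 30:40] = 2
        hm = np.zeros(labels.shape)
        hm[0:2, 4:12, 4:12] = 0.9
        hm[2:4, 30:40, 30:40] = 0.9
        hm[0:2, 30:38, 4:12] = 0.6   # spurious
        hm[2:4, 4:12, 30:38] = 0.6   # spurious
        truths.append(_mask(labels, ids))
        heatmaps.append(Heatmap(hm))
        # volume B: 1 lesion, missed entirely, 2 spurious
        labels = np.zeros((4, 48, 48), dtype=np.uint8)
        ids = np.zeros_like(labels, dtype=np.int32)
        labels[1:3, 10:20, 10:20] = 1
        ids[1:3, 10:20, 10:20] = 1
        hm = np.zeros(labels.shape)
        hm[0:2, 30:38, 30:38] = 0.6
        hm[2:4, 36:44, 4:12] = 0.6
        truths.append(_mask(labels, ids))
        heatmaps.append(Heatmap(hm))
        return heatmaps, truths

    def test_counts_on_constructed_fixture(self):
        heatmaps, truths = self._volumes()
        cfg = PostprocessGroup(min_cluster_voxels=20, median_window=3)
        curve = froc(heatmaps, truths, thresholds=np.array([0.5]), post_cfg=cfg)
        # 2 of 3 lesions hit; 4 spurious components over 2 volumes
        assert curve.tpr[0] == pytest.approx(2 / 3)
        assert curve.fpv[0] == pytest.approx(2.0)

    def test_perfect_predictions(self):
        labels = np.zeros((2, 32, 32), dtype=np.uint8)
        ids = np.zeros_like(labels, dtype=np.int32)
        labels[:, 8:16, 8:16] = 1
        ids[:, 8:16, 8:16] = 1
        truth = _mask(labels, ids)
        hm = Heatmap(labels.astype(float))
        curve = froc([hm], [truth], thresholds=np.array([0.9, 0.5, 0.1]))
        assert np.all(curve.tpr == 1.0)
        assert np.all(curve.fpv == 0.0)

    def test_empty_predictions(self):
        labels = np.zeros((2, 32, 32), dtype=np.uint8)
        ids = np.zeros_like(labels, dtype=np.int32)
        labels[:, 8:16, 8:16] = 1
        ids[:, 8:16, 8:16] = 1
        curve = froc([Heatmap(np.zeros(labels.shape))], [_mask(labels, ids)])
        assert np.all(curve.tpr == 0.0)
        assert np.all(curve.fpv == 0.0)

    def test_tpr_monotone_as_threshold_decreases(self):
        rng = np.random.default_rng(5)
        labels = np.zeros((4, 40, 40), dtype=np.uint8)
        ids = np.zeros_like(labels, dtype=np.int32)
        labels[1:3, 10:22, 10:22] = 1
        ids[1:3, 10:22, 10:22] = 1
        hm = np.clip(labels * rng.random(labels.shape) + 0.2 * rng.random(labels.shape), 0, 1)
        curve = froc([Heatmap(hm)], [_mask(labels, ids)],
                     post_cfg=PostprocessGroup(min_cluster_voxels=10))
        assert np.all(np.diff(curve.thresholds) < 0)
        assert np.all(np.diff(curve.tpr) >= 0)


class TestCrossvalReport:
    def test_identical_folds_zero_sd(self):
        rep = crossval_report([{"acc": 0.9}, {"acc": 0.9}, {"acc": 0.9}])
        assert rep["acc"]["mean"] == pytest.approx(0.9)
        assert rep["acc"]["sd"] == 0.0

    def test_single_fold_mean(self):
        rep = crossval_report([{"dice": 0.7}])
        assert rep["dice"]["mean"] == pytest.approx(0.7)

    def test_two_fold_sample_sd(self, tmp_path):
        rep = crossval_report(
            [{"acc": 0.8}, {"acc": 0.9}], out_csv=tmp_path / "cv.csv"
        )
        assert rep["acc"]["mean"] == pytest.approx(0.85)
        assert rep["acc"]["sd"] == pytest.approx(np.std([0.8, 0.9], ddof=1))
        assert (tmp_path / "cv.csv").exists()


def test_dice_of_identical_masks():
    rng = np.random.default_rng(7)
    m = (rng.random((2, 8, 8)) > 0.5).astype(np.uint8)
    assert dice_coefficient(_mask(m), _mask(m)) == pytest.approx(1.0)
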