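"""Evaluation surface: voxel-level ACC/SEN/SPE and ROC-AUC, lesion-level
FROC (true-positive rate vs false positives per volume), and the
cross-validation summary.

A ground-truth lesion counts as identified when at least one voxel of a
predicted connected component overlaps it (the default match rule;
overlap-fraction and centroid-in-mask alternatives are provided).  Each
predicted component overlapping no lesion is one false positive.  The
FROC sweep applies the full postprocessing chain (cluster removal,
smoothing) at every threshold so the curve reflects the deployed
pipeline.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from sklearn.metrics import roc_curve

from .config import EvaluationGroup, PostprocessGroup
from .postprocess import binarize, remove_small_clusters, smooth_boundaries, _STRUCTS_3D
from .volume import Heatmap, MaskVolume


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class FROCCurve:
    """Lesion-level operating points over a decreasing threshold sweep."""

    thresholds: np.ndarray  # strictly decreasing
    tpr: np.ndarray         # lesion true-positive rate, non-decreasing
    fpv: np.ndarray         # false-positive components per volume

    def tpr_at_fpv(self, max_fpv: float) -> float:
        """Best lesion TPR among operating points with FPV <= max_fpv."""
        ok = self.fpv <= max_fpv
        return float(self.tpr[ok].max()) if ok.any() else 0.0


def confusion(pred: MaskVolume, truth: MaskVolume) -> ConfusionCounts:
    """Voxelwise confusion counts between aligned binary volumes."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p = pred.labels.astype(bool)
    t = truth.labels.astype(bool)
    return ConfusionCounts(
        TP=int(np.sum(p & t)),
        FP=int(np.sum(p & ~t)),
        TN=int(np.sum(~p & ~t)),
        FN=int(np.sum(~p & t)),
    )


def acc_sen_spe(c: ConfusionCounts) -> tuple[float, float, float]:
    """ACC = (TP+TN)/total; SEN = TP/(TP+FN); SPE = TN/(TN+FP)."""
    if c.total == 0:
        raise ZeroDivisionError("ACC undefined: no voxels evaluated")
    if c.TP + c.FN == 0:
        raise ZeroDivisionError("SEN undefined: no positive ground-truth voxels")
    if c.TN + c.FP == 0:
        raise ZeroDivisionError("SPE undefined: no negative ground-truth voxels")
    acc = (c.TP + c.TN) / c.total
    sen = c.TP / (c.TP + c.FN)
    spe = c.TN / (c.TN + c.FP)
    return acc, sen, spe


def dice_coefficient(pred: MaskVolume, truth: MaskVolume) -> float:
    """Voxel Dice overlap 2|P∩T| / (|P|+|T|) between binary volumes."""
    c = confusion(pred, truth)
    den = 2 * c.TP + c.FP + c.FN
    if den == 0:
        raise ZeroDivisionError("Dice undefined: both volumes empty")
    return 2 * c.TP / den


def roc_auc(heatmap: Heatmap, truth: MaskVolume) -> float:
    """Voxel-level AUC via trapezoidal integration of the ROC curve.

    Numerically identical to the Mann-Whitney rank statistic
    P(score_pos > score_neg) + 0.5 P(tie).
    """
    t = truth.labels.ravel()
    if t.min() == t.max():
        raise ValueError("AUC undefined: ground truth contains a single class")
    s = heatmap.probabilities.ravel()
    fpr, tpr, _ = roc_curve(t, s)
    return float(np.trapezoid(tpr, fpr))


def _components(mask: MaskVolume, connectivity: int) -> tuple[np.ndarray, int]:
    return ndimage.label(mask.labels, structure=_STRUCTS_3D[connectivity])


def match_lesions(
    pred: MaskVolume,
    truth: MaskVolume,
    connectivity: int = 26,
    match_rule: str = "any_overlap",
    overlap_fraction: float = 0.3,
) -> tuple[int, int, int]:
    """Count (identified lesions, total lesions, false-positive components).

    A lesion is identified under ``any_overlap`` when any predicted
    component shares a voxel with it; under ``overlap_fraction`` when the
    shared voxels cover at least that fraction of the lesion; under
    ``centroid`` when some component's centroid lies inside the lesion.
    A component overlapping no lesion is one false positive.
    """
    if truth.lesion_ids is None:
        raise ValueError("truth volume carries no lesion instance ids")
    comp, n_comp = _components(pred, connectivity)
    lesion_ids = np.unique(truth.lesion_ids)
    lesion_ids = lesion_ids[lesion_ids > 0]
    hit = set()
    fp = 0
    for ci in range(1, n_comp + 1):
        cmask = comp == ci
        overlapped = np.unique(truth.lesion_ids[cmask])
        overlapped = overlapped[overlapped > 0]
        if overlapped.size == 0:
            fp += 1
            continue
        if match_rule == "centroid":
            centroid = tuple(int(round(v)) for v in ndimage.center_of_mass(cmask))
            if truth.lesion_ids[centroid] > 0:
                hit.add(int(truth.lesion_ids[centroid]))
            else:
                fp += 1
            continue
        matched_any = False
        for lid in overlapped:
            if match_rule == "any_overlap":
                hit.add(int(lid))
                matched_any = True
            elif match_rule == "overlap_fraction":
                lesion_vox = np.sum(truth.lesion_ids == lid)
                shared = np.sum(cmask & (truth.lesion_ids == lid))
                if shared / lesion_vox >= overlap_fraction:
                    hit.add(int(lid))
                    matched_any = True
            else:
                raise ValueError(f"unknown match rule '{match_rule}'")
        if not matched_any:
            fp += 1
    return len(hit), int(lesion_ids.size), fp


def froc(
    heatmaps: list[Heatmap],
    truths: list[MaskVolume],
    thresholds: np.ndarray | None = None,
    post_cfg: PostprocessGroup | None = None,
    eval_cfg: EvaluationGroup | None = None,
) -> FROCCurve:
    """Lesion-level FROC over a decreasing threshold sweep.

    At each threshold every volume is binarized and postprocessed, then
    lesions are matched per :func:`match_lesions`; TPR pools lesions over
    all volumes and FPV averages false-positive components per volume.
    """
    if len(heatmaps) != len(truths):
        raise ValueError("need one truth per heatmap")
    post_cfg = post_cfg or PostprocessGroup()
    eval_cfg = eval_cfg or EvaluationGroup()
    if thresholds is None:
        thresholds = np.linspace(0.95, 0.05, eval_cfg.n_froc_thresholds)
    thresholds = np.asarray(sorted(set(float(t) for t in thresholds), reverse=True))
    tprs, fpvs = [], []
    for thr in thresholds:
        n_hit = n_lesions = n_fp = 0
        for hm, truth in zip(heatmaps, truths):
            mask = binarize(hm, thr)
            mask = remove_small_clusters(
                mask, post_cfg.min_cluster_voxels, post_cfg.connectivity, post_cfg.cluster_mode
            )
            mask = smooth_boundaries(mask, post_cfg.median_window)
            h, n, fp = match_lesions(
                mask, truth, post_cfg.connectivity, eval_cfg.match_rule, eval_cfg.overlap_fraction
            )
            n_hit += h
            n_lesions += n
            n_fp += fp
        tprs.append(n_hit / n_lesions if n_lesions else 0.0)
        fpvs.append(n_fp / len(heatmaps))
    return FROCCurve(thresholds, np.asarray(tprs), np.asarray(fpvs))


def crossval_report(
    fold_metrics: list[dict[str, float]],
    out_csv: str | Path | None = None,
) -> dict[str, dict[str, float]]:
    """Per-metric mean and sample standard deviation over folds.

    Returns ``{metric: {"mean": m, "sd": s}}``; with a single fold the sd
    is reported as 0.  Optionally writes a per-fold CSV.
    """
    if not fold_metrics:
        raise ValueError("at least one completed fold required")
    keys = sorted(fold_metrics[0])
    summary: dict[str, dict[str, float]] = {}
    for key in keys:
        vals = np.array([m[key] for m in fold_metrics], dtype=float)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        summary[key] = {"mean": float(vals.mean()), "sd": sd}
    if out_csv is not None:
        out_csv = Path(out_csv)
        out_csv.parent.mkdir(parents=True, exist_ok=True)
        with open(out_csv, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["fold"] + keys)
            for i, m in enumerate(fold_metrics):
                writer.writerow([i] + [m[k] for k in keys])
            writer.writerow(["mean"] + [summary[k]["mean"] for k in keys])
            writer.writerow(["sd"] + [summary[k]["sd"] for k in keys])
    return summary


def write_froc_csv(curve: FROCCurve, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["threshold", "lesion_tpr", "fpv"])
        for t, tp, fp in zip(curve.thresholds, curve.tpr, curve.fpv):
            writer.writerow([t, tp, fp])
    return path
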