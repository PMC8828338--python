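"""Scikit-learn style estimator wrapping the full segmentation pipeline.

``DilatedFCNSegmenter`` composes preprocessing (top-hat + RBF
constraint), sliding-window patch extraction, dilated-FCN training with
the f_alpha (Dice) loss under Adagrad, dense per-slice prediction, and
cluster-size postprocessing.  It follows the estimator contract —
``fit`` / ``predict`` / ``predict_proba`` / ``score``, ``get_params`` /
``set_params``, fitted attributes with a trailing underscore — so it
composes with sklearn model selection; note that samples here are whole
image volumes, not rows of a feature matrix.

Defaults are the desk-scale profile (patch 64, stride 16, small epoch
budget) that trains in minutes on one CPU; :func:`paper_scale_params`
returns the published full-scale operating point (patch 256, stride 28,
batch 150, 1000 x 1000 schedule).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .config import PostprocessGroup, PreprocessGroup, TrainingGroup
from .network import build_network, default_architecture, predict_heatmap
from .patches import extract_patches
from .postprocess import postprocess
from .preprocess import preprocess_volume
from .training import train
from .volume import Heatmap, ImageVolume, MaskVolume


def _as_volume(x, pixel_spacing_mm: float, slice_spacing_mm: float) -> ImageVolume:
    if isinstance(x, ImageVolume):
        return x
    return ImageVolume(np.asarray(x), pixel_spacing_mm, slice_spacing_mm)


def _as_mask(y, pixel_spacing_mm: float, slice_spacing_mm: float) -> MaskVolume:
    if isinstance(y, MaskVolume):
        return y
    return MaskVolume(np.asarray(y), None, pixel_spacing_mm, slice_spacing_mm)


def paper_scale_params() -> dict:
    """The published full-scale configuration as estimator params."""
    return dict(
        patch_size=256, stride=28, batch_size=150, batches_per_epoch=1000,
        epochs=1000, tophat_radius_px=50,
    )


class DilatedFCNSegmenter(BaseEstimator):
    """End-to-end mass-region segmenter for image volumes.

    Parameters
    ----------
    patch_size, stride : int
        Sliding-window geometry for training patches.
    hidden_channels, dilations, kernel_size : network architecture.
    alpha : float
        Exponent of the f_alpha overlap loss (1 = Dice).
    learning_rate, batch_size, batches_per_epoch, epochs : Adagrad schedule.
    threshold, min_cluster_voxels, connectivity, median_window :
        postprocessing of predicted heatmaps.
    tophat_radius_px, delta_mm, candidate_percentile, min_separation_mm,
    enable_tophat, enable_constraint : preprocessing.
    augment : bool
        Right-angle rotation augmentation of each epoch's balanced draw.
    random_state : int
        Master seed for weight init and epoch sampling.
    """

    def __init__(
        self,
        patch_size: int = 64,
        stride: int = 16,
        hidden_channels: int = 32,
        dilations: tuple[int, ...] = (1, 1, 2, 4, 8, 16, 1),
        kernel_size: int = 3,
        alpha: float = 1.0,
        learning_rate: float = 0.01,
        batch_size: int = 16,
        batches_per_epoch: int = 30,
        epochs: int = 15,
        smooth_eps: float = 1e-6,
        threshold: float = 0.5,
        min_cluster_voxels: int = 50,
        connectivity: int = 26,
        median_window: int = 3,
        tophat_radius_px: int = 35,
        delta_mm: float = 5.0,
        candidate_percentile: float = 99.5,
        min_separation_mm: float = 10.0,
        enable_tophat: bool = True,
        enable_constraint: bool = True,
        augment: bool = True,
        pixel_spacing_mm: float = 0.1,
        slice_spacing_mm: float = 1.0,
        random_state: int = 0,
    ):
        self.patch_size = patch_size
        self.stride = stride
        self.hidden_channels = hidden_channels
        self.dilations = dilations
        self.kernel_size = kernel_size
        self.alpha = alpha
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.batches_per_epoch = batches_per_epoch
        self.epochs = epochs
        self.smooth_eps = smooth_eps
        self.threshold = threshold
        self.min_cluster_voxels = min_cluster_voxels
        self.connectivity = connectivity
        self.median_window = median_window
        self.tophat_radius_px = tophat_radius_px
        self.delta_mm = delta_mm
        self.candidate_percentile = candidate_percentile
        self.min_separation_mm = min_separation_mm
        self.enable_tophat = enable_tophat
        self.enable_constraint = enable_constraint
        self.augment = augment
        self.pixel_spacing_mm = pixel_spacing_mm
        self.slice_spacing_mm = slice_spacing_mm
        self.random_state = random_state

    # -- config assembly ---------------------------------------------------

    def _preprocess_cfg(self) -> PreprocessGroup:
        return PreprocessGroup(
            tophat_radius_px=self.tophat_radius_px,
            delta_mm=self.delta_mm,
            candidate_percentile=self.candidate_percentile,
            min_separation_mm=self.min_separation_mm,
            enable_tophat=self.enable_tophat,
            enable_constraint=self.enable_constraint,
        )

    def _training_cfg(self) -> TrainingGroup:
        return TrainingGroup(
            batch_size=self.batch_size,
            batches_per_epoch=self.batches_per_epoch,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            alpha=self.alpha,
            smooth_eps=self.smooth_eps,
        )

    def _postprocess_cfg(self) -> PostprocessGroup:
        return PostprocessGroup(
            threshold=self.threshold,
            min_cluster_voxels=self.min_cluster_voxels,
            connectivity=self.connectivity,
            median_window=self.median_window,
        )

    def _architecture(self):
        return default_architecture(
            hidden_channels=self.hidden_channels,
            dilations=tuple(self.dilations),
            kernel_size=self.kernel_size,
        )

    def _preprocess_all(self, X) -> list[ImageVolume]:
        cfg = self._preprocess_cfg()
        vols = [_as_volume(x, self.pixel_spacing_mm, self.slice_spacing_mm) for x in X]
        return [preprocess_volume(v, cfg) for v in vols]

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        """Train on volumes X with ground-truth masks y.

        X : sequence of ImageVolume or (slices, rows, cols) arrays.
        y : sequence of MaskVolume or binary arrays of the same shapes.
        """
        if len(X) != len(y):
            raise ValueError("X and y must have the same number of volumes")
        masks = [_as_mask(m, self.pixel_spacing_mm, self.slice_spacing_mm) for m in y]
        processed = self._preprocess_all(X)
        all_patches = []
        for vol, mask in zip(processed, masks):
            all_patches.extend(extract_patches(vol, mask, self.patch_size, self.stride))
        self.model_ = build_network(self._architecture(), seed=self.random_state)
        self.loss_trace_ = train(
            self.model_, all_patches, self._training_cfg(),
            seed=self.random_state, augment=self.augment,
        )
        self.n_patches_ = len(all_patches)
        self.classes_ = np.array([0, 1])
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit() first")

    def predict_proba(self, X) -> list[Heatmap]:
        """Dense per-voxel mass-class probability heatmaps."""
        self._check_fitted()
        return [predict_heatmap(self.model_, v) for v in self._preprocess_all(X)]

    def predict(self, X) -> list[MaskVolume]:
        """Final binary masks: threshold, cluster removal, median smoothing."""
        cfg = self._postprocess_cfg()
        return [postprocess(hm, cfg) for hm in self.predict_proba(X)]

    def score(self, X, y) -> float:
        """Mean voxel Dice of predicted masks against ground truth."""
        from .evaluate import dice_coefficient

        masks = [_as_mask(m, self.pixel_spacing_mm, self.slice_spacing_mm) for m in y]
        preds = self.predict(X)
        dices = []
        for p, t in zip(preds, masks):
            try:
                dices.append(dice_coefficient(p, t))
            except ZeroDivisionError:
                dices.append(1.0)  # both empty: trivially perfect
        return float(np.mean(dices))
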