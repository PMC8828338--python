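"""From probability heatmaps to final masks.

Threshold at 0.5, remove connected clusters of fewer than 50 voxels
(strict "< 50": a 50-voxel cluster survives), then smooth boundaries
with a per-slice binary median filter.  Cluster connectivity defaults to
26-neighbourhood in 3D ("voxels in volumes"); a per-slice 2D mode is
available.  Removal precedes smoothing and the mask is not re-filtered
afterwards, so smoothing may legitimately shrink a surviving component
below the voxel threshold.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .config import PostprocessGroup
from .volume import Heatmap, MaskVolume


_STRUCTS_3D = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def binarize(heatmap: Heatmap, threshold: float = 0.5) -> MaskVolume:
    """Voxel = 1 iff probability >= threshold (boundary inclusive)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    labels = (heatmap.probabilities >= threshold).astype(np.uint8)
    return MaskVolume(labels, None, heatmap.pixel_spacing_mm, heatmap.slice_spacing_mm)


def remove_small_clusters(
    mask: MaskVolume, min_voxels: int = 50, connectivity: int = 26, mode: str = "3d"
) -> MaskVolume:
    """Zero out connected components with fewer than ``min_voxels`` voxels.

    Components of exactly ``min_voxels`` voxels are retained.
    """
    if connectivity not in _STRUCTS_3D:
        raise ValueError("connectivity must be 6, 18 or 26")
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    out = np.zeros_like(mask.labels)
    if mode == "3d":
        lab, n = ndimage.label(mask.labels, structure=_STRUCTS_3D[connectivity])
        if n:
            sizes = np.bincount(lab.ravel())
            keep = np.flatnonzero(sizes >= min_voxels)
            keep = keep[keep > 0]
            out[np.isin(lab, keep)] = 1
    elif mode == "2d":
        s2d = ndimage.generate_binary_structure(2, 2)
        for s in range(mask.labels.shape[0]):
            lab, n = ndimage.label(mask.labels[s], structure=s2d)
            if n:
                sizes = np.bincount(lab.ravel())
                keep = np.flatnonzero(sizes >= min_voxels)
                keep = keep[keep > 0]
                out[s][np.isin(lab, keep)] = 1
    else:
        raise ValueError("mode must be '3d' or '2d'")
    return MaskVolume(out, None, mask.pixel_spacing_mm, mask.slice_spacing_mm)


def smooth_boundaries(mask: MaskVolume, window: int = 3) -> MaskVolume:
    """Per-slice 2D binary median filter with an odd square window."""
    if window < 3 or window % 2 == 0:
        raise ValueError("median window must be odd and >= 3")
    out = np.empty_like(mask.labels)
    for s in range(mask.labels.shape[0]):
        out[s] = ndimage.median_filter(mask.labels[s], size=window, mode="reflect")
    return MaskVolume(out, None, mask.pixel_spacing_mm, mask.slice_spacing_mm)


def postprocess(heatmap: Heatmap, cfg: PostprocessGroup) -> MaskVolume:
    """threshold -> cluster removal -> median smoothing, in that order."""
    cfg.validate()
    mask = binarize(heatmap, cfg.threshold)
    mask = remove_small_clusters(
        mask, cfg.min_cluster_voxels, cfg.connectivity, cfg.cluster_mode
    )
    return smooth_boundaries(mask, cfg.median_window)
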