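"""Patch-level training set construction.

Sliding-window extraction over every slice, center-pixel labelling
(positive iff the mask is 1 at the patch centre), class-balanced
resampling per epoch, and right-angle rotation augmentation.

The centre of an even-sized patch is the pixel at offset ``P // 2`` from
the origin on each axis (floor convention); patch origins are top-left
corners and all windows are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import ImageVolume, MaskVolume


@dataclass
class Patch:
    """A square sub-image with its dense mask, origin, label and rotation."""

    pixels: np.ndarray            # (P, P) float32
    mask: np.ndarray              # (P, P) uint8 — dense target for the Dice loss
    origin: tuple[int, int, int]  # (slice, row, col) of the top-left corner
    label: int                    # mask value at the central pixel
    rotation: int = 0             # degrees in {0, 90, 180, 270}


def enumerate_origins(
    height: int, width: int, patch_size: int, stride: int
) -> list[tuple[int, int]]:
    """Row-major top-left corners of all stride-aligned windows inside the slice.

    count = (floor((H-P)/s)+1) * (floor((W-P)/s)+1).
    """
    if patch_size > min(height, width):
        raise ValueError(
            f"patch_size {patch_size} exceeds slice extent ({height}, {width})"
        )
    if stride < 1:
        raise ValueError("stride must be >= 1")
    rows = range(0, height - patch_size + 1, stride)
    cols = range(0, width - patch_size + 1, stride)
    return [(r, c) for r in rows for c in cols]


def extract_patches(
    vol: ImageVolume,
    mask: MaskVolume,
    patch_size: int,
    stride: int,
) -> list[Patch]:
    """One Patch per (slice, origin); label from the mask at the patch centre.

    Both classes are retained — negatives far from any mass carry useful
    background context for the classifier.
    """
    if vol.shape != mask.shape:
        raise ValueError(f"volume shape {vol.shape} != mask shape {mask.shape}")
    n_s, n_r, n_c = vol.shape
    origins = enumerate_origins(n_r, n_c, patch_size, stride)
    half = patch_size // 2
    vox = vol.voxels.astype(np.float32)
    out: list[Patch] = []
    for s in range(n_s):
        for r, c in origins:
            label = int(mask.labels[s, r + half, c + half])
            out.append(
                Patch(
                    pixels=vox[s, r : r + patch_size, c : c + patch_size].copy(),
                    mask=mask.labels[s, r : r + patch_size, c : c + patch_size].copy(),
                    origin=(s, r, c),
                    label=label,
                )
            )
    return out


def balanced_epoch_sample(
    patches: list[Patch], per_class_n: int, seed: int
) -> list[Patch]:
    """Draw exactly ``per_class_n`` positives and negatives for one epoch.

    Classes with at least ``per_class_n`` members are sampled without
    replacement, smaller classes with replacement.  Deterministic under
    the seed.
    """
    if per_class_n < 1:
        raise ValueError("per_class_n must be >= 1")
    pos = [p for p in patches if p.label == 1]
    neg = [p for p in patches if p.label == 0]
    if not pos:
        raise ValueError("no positive patches available for balanced sampling")
    if not neg:
        raise ValueError("no negative patches available for balanced sampling")
    rng = np.random.default_rng(seed)
    out: list[Patch] = []
    for group in (pos, neg):
        replace = len(group) < per_class_n
        idx = rng.choice(len(group), size=per_class_n, replace=replace)
        out.extend(group[i] for i in idx)
    return out


def augment_rotations(patch: Patch) -> list[Patch]:
    """The four right-angle rotations of a square patch; labels preserved."""
    p = patch.pixels
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError(f"patch must be square 2D, got shape {p.shape}")
    out = []
    for k, deg in enumerate((0, 90, 180, 270)):
        out.append(
            Patch(
                pixels=np.ascontiguousarray(np.rot90(patch.pixels, k)),
                mask=np.ascontiguousarray(np.rot90(patch.mask, k)),
                origin=patch.origin,
                label=patch.label,
                rotation=deg,
            )
        )
    return out
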