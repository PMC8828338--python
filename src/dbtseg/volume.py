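"""Image, mask and heatmap volume containers plus TIFF-stack I/O.

A volume is a stack of 2D grayscale slices (one TIFF page per slice) with
spatial metadata: the in-plane pixel pitch and the spacing between
reconstructed slices, both in millimetres.  Tomosynthesis stacks are
strongly anisotropic (sub-millimetre pixels, ~1 mm slice spacing), so the
two spacings are carried separately and every physical-distance
computation in the package converts through them explicitly.

Indexing convention: 0-based ``(slice, row, col)`` everywhere; window
ranges are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile


class VolumeError(ValueError):
    """Raised for malformed volumes or volume files."""


@dataclass
class ImageVolume:
    """A grayscale image volume.

    Parameters
    ----------
    voxels : ndarray, shape (n_slices, n_rows, n_cols)
        Non-negative, finite intensities.
    pixel_spacing_mm : float
        In-plane millimetres per pixel.
    slice_spacing_mm : float
        Millimetres between adjacent slices.
    """

    voxels: np.ndarray
    pixel_spacing_mm: float = 0.1
    slice_spacing_mm: float = 1.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise VolumeError(f"voxels must be 3D (slice,row,col), got ndim={self.voxels.ndim}")
        if self.voxels.shape[0] < 1:
            raise VolumeError("volume must have at least one slice")
        if not np.all(np.isfinite(self.voxels)):
            bad = np.argwhere(~np.isfinite(self.voxels))[0]
            raise VolumeError(f"non-finite voxel at (slice,row,col)={tuple(int(i) for i in bad)}")
        if np.any(self.voxels < 0):
            bad = np.argwhere(self.voxels < 0)[0]
            raise VolumeError(f"negative voxel at (slice,row,col)={tuple(int(i) for i in bad)}")
        if not (self.pixel_spacing_mm > 0 and self.slice_spacing_mm > 0):
            raise VolumeError("pixel_spacing_mm and slice_spacing_mm must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def normalized(self) -> "ImageVolume":
        """Return a copy with intensities scaled to [0, 1] by the volume max."""
        vmax = float(self.voxels.max())
        vox = self.voxels.astype(np.float64)
        if vmax > 0:
            vox = vox / vmax
        return ImageVolume(vox, self.pixel_spacing_mm, self.slice_spacing_mm)


@dataclass
class MaskVolume:
    """Binary per-voxel labels aligned to an :class:`ImageVolume`.

    ``lesion_ids`` optionally partitions the positive voxels into lesion
    instances (0 = background, k > 0 = lesion instance k).
    """

    labels: np.ndarray
    lesion_ids: np.ndarray | None = None
    pixel_spacing_mm: float = 0.1
    slice_spacing_mm: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise VolumeError(f"labels must be 3D, got ndim={self.labels.ndim}")
        vals = np.unique(self.labels)
        if not np.all(np.isin(vals, [0, 1])):
            raise VolumeError(f"labels must be binary {{0,1}}, found values {vals[:5]}")
        self.labels = self.labels.astype(np.uint8)
        if self.lesion_ids is not None:
            self.lesion_ids = np.asarray(self.lesion_ids)
            if self.lesion_ids.shape != self.labels.shape:
                raise VolumeError("lesion_ids shape differs from labels shape")
            if np.any(self.lesion_ids < 0):
                raise VolumeError("lesion_ids must be non-negative")
            if not np.array_equal(self.lesion_ids > 0, self.labels == 1):
                raise VolumeError("lesion_ids must be positive exactly where labels == 1")
            self.lesion_ids = self.lesion_ids.astype(np.int32)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def n_lesions(self) -> int:
        if self.lesion_ids is None:
            return int(self.labels.max())
        ids = np.unique(self.lesion_ids)
        return int((ids > 0).sum())


@dataclass
class Heatmap:
    """Dense per-voxel mass-class probabilities, aligned to a source volume."""

    probabilities: np.ndarray
    pixel_spacing_mm: float = 0.1
    slice_spacing_mm: float = 1.0

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        if self.probabilities.ndim != 3:
            raise VolumeError("probabilities must be 3D")
        if self.probabilities.size and not (
            np.nanmin(self.probabilities) >= 0.0 and np.nanmax(self.probabilities) <= 1.0
        ):
            raise VolumeError("probabilities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.probabilities.shape


def read_volume(
    path: str | Path,
    pixel_spacing_mm: float = 0.1,
    slice_spacing_mm: float = 1.0,
    normalize: bool = False,
) -> ImageVolume:
    """Read a multi-page grayscale TIFF stack into an :class:`ImageVolume`.

    One slice per TIFF page; intensities are cast to floating point.  The
    spatial metadata is supplied by the caller (TIFF tags are not trusted
    to carry it).  With ``normalize=True`` intensities are rescaled to
    [0, 1] by the per-volume maximum.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    pages = []
    with tifffile.TiffFile(path) as tif:
        for i, page in enumerate(tif.pages):
            arr = page.asarray()
            if arr.ndim != 2:
                raise VolumeError(f"page {i} of {path} is not single-channel grayscale (ndim={arr.ndim})")
            if pages and arr.shape != pages[0].shape:
                raise VolumeError(
                    f"page {i} of {path} has shape {arr.shape}, expected {pages[0].shape}"
                )
            pages.append(arr)
    if not pages:
        raise VolumeError(f"no pages in TIFF {path}")
    vox = np.stack(pages).astype(np.float64)
    vol = ImageVolume(vox, pixel_spacing_mm, slice_spacing_mm)
    return vol.normalized() if normalize else vol


def read_mask(
    path: str | Path,
    pixel_spacing_mm: float = 0.1,
    slice_spacing_mm: float = 1.0,
) -> MaskVolume:
    """Read a binary mask TIFF stack (any nonzero voxel counts as positive)."""
    vol = read_volume(path, pixel_spacing_mm, slice_spacing_mm, normalize=False)
    return MaskVolume((vol.voxels > 0).astype(np.uint8), None, pixel_spacing_mm, slice_spacing_mm)


def write_volume(vol: ImageVolume | MaskVolume, path: str | Path) -> Path:
    """Write a volume as a multi-page TIFF, one page per slice.

    Masks are written as {0,1} uint8 pages.  Integer image volumes are
    written with their dtype preserved (bit-exact round trip); float
    volumes are written as float32.  NaN/Inf voxels are refused.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(vol, MaskVolume):
        data = vol.labels.astype(np.uint8)
    else:
        data = vol.voxels
        if not np.all(np.isfinite(data)):
            bad = np.argwhere(~np.isfinite(data))[0]
            raise VolumeError(
                f"refusing to write non-finite voxel at (slice,row,col)={tuple(int(i) for i in bad)}"
            )
        if not np.issubdtype(data.dtype, np.integer):
            data = data.astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")
    return path
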