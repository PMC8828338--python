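"""Synthetic tomosynthesis-like phantoms with per-lesion ground truth.

The generator emulates the statistical structure the segmentation method
assumes: a smooth tissue-texture background, low-contrast bright masses
with diffuse margins, and Poisson (photon-counting) noise.  It makes no
attempt at anatomical realism or reconstruction artifacts; its purpose is
to provide seeded, labelled volumes so every stage of the pipeline is
testable without clinical data.

Lesions are ellipsoids with a raised-cosine edge: intensity inside a
lesion is elevated multiplicatively over the local background by the
configured fractional contrast, ramping smoothly to zero across the
margin.  The binary mask marks the voxels within the nominal ellipsoid
(where the elevation is at least half its peak), so mask boundaries sit
mid-ramp — as diffuse as the masses themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volume import ImageVolume, MaskVolume


class PlacementError(RuntimeError):
    """Raised when lesions cannot be placed without overlap."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic volume.

    ``contrast`` is the fractional intensity elevation of a lesion over
    its local background (0.4 = 40% brighter at the lesion core).
    ``photon_count`` is the expected photon count at unit intensity; the
    clean image is scaled to photons, Poisson noise drawn, and the result
    rescaled, so larger values mean less noise.
    """

    shape: tuple[int, int, int] = (16, 128, 128)
    n_lesions: int = 2
    diameter_range_mm: tuple[float, float] = (2.5, 5.0)
    contrast: float = 0.4
    background_sigma_px: float = 8.0
    photon_count: float = 1000.0
    pixel_spacing_mm: float = 0.1
    slice_spacing_mm: float = 1.0
    edge_fraction: float = 0.3   # raised-cosine margin width, fraction of radius
    seed: int = 0

    def validate(self) -> None:
        ns, nr, nc = self.shape
        if ns < 1 or nr < 1 or nc < 1:
            raise ValueError("shape entries must be >= 1")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        lo, hi = self.diameter_range_mm
        min_extent_mm = min(
            ns * self.slice_spacing_mm, nr * self.pixel_spacing_mm, nc * self.pixel_spacing_mm
        )
        if not (0 < lo <= hi < min_extent_mm):
            raise ValueError(
                f"diameter range ({lo}, {hi}) mm must lie within (0, {min_extent_mm}) mm "
                "(the smallest volume extent)"
            )
        if self.contrast <= 0:
            raise ValueError("contrast must be > 0")
        if self.photon_count <= 0:
            raise ValueError("photon_count must be > 0")
        if not 0 < self.edge_fraction < 1:
            raise ValueError("edge_fraction must lie in (0, 1)")


def _background(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth tissue texture: blurred white noise, mapped to [0.2, 0.6]."""
    noise = rng.standard_normal(spec.shape)
    sig_z = max(spec.background_sigma_px * spec.pixel_spacing_mm / spec.slice_spacing_mm, 0.5)
    tex = ndimage.gaussian_filter(noise, sigma=(sig_z, spec.background_sigma_px, spec.background_sigma_px))
    tmin, tmax = tex.min(), tex.max()
    if tmax > tmin:
        tex = (tex - tmin) / (tmax - tmin)
    else:
        tex = np.full(spec.shape, 0.5)
    return 0.2 + 0.4 * tex


def _lesion_geometry(spec: PhantomSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sample semi-axes (voxels, zyx order) for one ellipsoidal lesion."""
    lo, hi = spec.diameter_range_mm
    d_mm = rng.uniform(lo, hi)
    # mild in-plane eccentricity so lesions are not perfect spheres
    ecc = rng.uniform(0.85, 1.15)
    r_row = 0.5 * d_mm * ecc / spec.pixel_spacing_mm
    r_col = 0.5 * d_mm / ecc / spec.pixel_spacing_mm
    r_slc = 0.5 * d_mm / spec.slice_spacing_mm
    semi = np.array([max(r_slc, 0.6), r_row, r_col])
    return semi, np.array([d_mm])


def _place_lesions(
    spec: PhantomSpec, rng: np.random.Generator, max_tries: int = 200
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Place non-overlapping ellipsoids; returns (center_zyx, semi_axes_zyx)."""
    placed: list[tuple[np.ndarray, np.ndarray]] = []
    dims = np.array(spec.shape, dtype=float)
    for k in range(spec.n_lesions):
        for _ in range(max_tries):
            # fresh geometry each try: a smaller lesion may fit where a
            # large one cannot
            semi, _ = _lesion_geometry(spec, rng)
            margin = semi * (1 + spec.edge_fraction) + 1
            if np.any(dims - 2 * margin <= 0):
                continue
            center = np.array([rng.uniform(m, d - m) for m, d in zip(margin, dims)])
            ok = True
            for c2, s2 in placed:
                # conservative separation: sum of outer radii along the center line
                gap = np.linalg.norm((center - c2) / (semi + s2))
                if gap < 1 + spec.edge_fraction:
                    ok = False
                    break
            if ok:
                placed.append((center, semi))
                break
        else:
            raise PlacementError(
                f"failed to place lesion {k + 1}/{spec.n_lesions} after {max_tries} tries "
                f"in volume {spec.shape}"
            )
    return placed


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, MaskVolume]:
    """Generate one seeded phantom volume with its ground-truth mask.

    Identical specs (including seed) produce bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    bg = _background(spec, rng)
    lesions = _place_lesions(spec, rng)

    elevation = np.zeros(spec.shape)
    labels = np.zeros(spec.shape, dtype=np.uint8)
    lesion_ids = np.zeros(spec.shape, dtype=np.int32)
    zz, yy, xx = np.meshgrid(*(np.arange(n, dtype=float) for n in spec.shape), indexing="ij")
    for k, (center, semi) in enumerate(lesions, start=1):
        rho = np.sqrt(
            ((zz - center[0]) / semi[0]) ** 2
            + ((yy - center[1]) / semi[1]) ** 2
            + ((xx - center[2]) / semi[2]) ** 2
        )
        e = spec.edge_fraction
        w = np.zeros(spec.shape)
        inner = rho <= 1 - e
        ramp = (rho > 1 - e) & (rho <= 1 + e)
        w[inner] = 1.0
        w[ramp] = 0.5 * (1 + np.cos(np.pi * (rho[ramp] - (1 - e)) / (2 * e)))
        elevation = np.maximum(elevation, w)
        inside = rho <= 1.0
        labels[inside] = 1
        lesion_ids[inside] = k

    clean = bg * (1 + spec.contrast * elevation)
    counts = rng.poisson(np.maximum(clean, 0) * spec.photon_count)
    noisy = counts / spec.photon_count
    vmax = noisy.max()
    if vmax > 0:
        noisy = noisy / vmax

    vol = ImageVolume(noisy, spec.pixel_spacing_mm, spec.slice_spacing_mm)
    mask = MaskVolume(labels, lesion_ids, spec.pixel_spacing_mm, spec.slice_spacing_mm)
    return vol, mask


def generate_dataset(
    n_volumes: int,
    spec_template: PhantomSpec,
    seed: int,
    lesion_range: tuple[int, int] = (1, 3),
) -> list[tuple[ImageVolume, MaskVolume]]:
    """Generate a dataset of phantoms with per-volume seeds derived from ``seed``.

    The lesion count of each volume is drawn uniformly from
    ``lesion_range`` (inclusive).  Deterministic: the same master seed
    yields the identical dataset.
    """
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_volumes)]
    count_rng = np.random.default_rng(ss.generate_state(1)[0] % (2**31) + 1)
    out = []
    for i in range(n_volumes):
        n_les = int(count_rng.integers(lesion_range[0], lesion_range[1] + 1))
        spec = replace(spec_template, seed=child_seeds[i], n_lesions=n_les)
        try:
            out.append(generate_phantom(spec))
        except PlacementError as err:
            raise PlacementError(f"volume {i}: {err}") from err
    return out
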