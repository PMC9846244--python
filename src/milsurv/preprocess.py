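"""Tissue segmentation, non-overlapping 256x256 tiling, patch encoding.

The segmentation follows the standard weakly-supervised WSI recipe: convert
to HSV, median-filter the saturation channel (tissue is saturated, glass
background is not), binarize at a saturation threshold, morphologically
close, and drop small connected components.  Tiling lays a regular grid
anchored at (0, 0) over the mask and keeps cells whose tissue fraction
clears a threshold; partial border cells are discarded.  Encoding maps each
retained patch to a fixed-length feature vector through a pluggable encoder
contract — any callable producing a deterministic fixed-length vector from
a patch qualifies, so a pretrained CNN backend can slot in behind the same
interface.  The operations here run on a single resolution level (level 0,
the highest, for pyramidal sources read through an adapter).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.morphology import closing, footprint_rectangle

from .data import PatchBag

__all__ = [
    "SegmentationParams",
    "TissueMask",
    "PatchGrid",
    "segment_tissue",
    "tile_patches",
    "encode_patches",
    "StatsEncoder",
]


@dataclass
class SegmentationParams:
    sat_threshold: float = 0.08
    median_blur_k: int = 5
    close_k: int = 5
    min_area: int = 64


@dataclass
class TissueMask:
    mask: np.ndarray  # bool, same H x W as the source image
    params: SegmentationParams

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class PatchGrid:
    """Retained grid cells: (x, y) top-left corners, 0-based, x = column."""

    patch_size: int
    coords: np.ndarray           # (K, 2) int
    tissue_fraction: np.ndarray  # (K,)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)
        self.tissue_fraction = np.asarray(self.tissue_fraction, dtype=float)

    @property
    def n_patches(self) -> int:
        return self.coords.shape[0]


def segment_tissue(
    rgb_image: np.ndarray, params: SegmentationParams | None = None
) -> TissueMask:
    """HSV-saturation thresholding pipeline for tissue-vs-glass segmentation."""
    params = params or SegmentationParams()
    img = np.asarray(rgb_image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected a 3-channel RGB image")
    if img.dtype != np.uint8:
        raise ValueError("expected an 8-bit image")
    sat = rgb2hsv(img)[..., 1]
    sat = ndimage.median_filter(sat, size=params.median_blur_k)
    mask = sat > params.sat_threshold
    if params.close_k > 1:
        mask = closing(
            mask, footprint_rectangle((params.close_k, params.close_k))
        ).astype(bool)
    if params.min_area > 0:
        labels, n = ndimage.label(mask)
        if n:
            sizes = np.bincount(labels.ravel())
            small = np.flatnonzero(sizes < params.min_area)
            mask &= ~np.isin(labels, small[small > 0])
    return TissueMask(mask=mask, params=params)


def tile_patches(
    tissue: TissueMask | np.ndarray,
    patch_size: int = 256,
    min_tissue_fraction: float = 0.5,
) -> PatchGrid:
    """Non-overlapping grid over the mask; keep cells with enough tissue."""
    if patch_size < 1:
        raise ValueError("patch_size must be >= 1")
    mask = tissue.mask if isinstance(tissue, TissueMask) else np.asarray(tissue)
    h, w = mask.shape
    coords, fracs = [], []
    for y in range(0, h - patch_size + 1, patch_size):
        for x in range(0, w - patch_size + 1, patch_size):
            frac = float(mask[y:y + patch_size, x:x + patch_size].mean())
            if frac >= min_tissue_fraction:
                coords.append((x, y))
                fracs.append(frac)
    return PatchGrid(
        patch_size=patch_size,
        coords=np.array(coords, dtype=np.int64).reshape(-1, 2),
        tissue_fraction=np.array(fracs),
    )


class StatsEncoder:
    """Deterministic test encoder: per-channel pixel statistics, randomly
    projected to ``dim`` dimensions with a seeded matrix.

    Satisfies the encoder contract (patch -> fixed-length vector,
    deterministic given its configuration) without any pretrained weights.
    """

    #: per channel: mean, std, min, max, 25/50/75th percentiles, 8-bin histogram
    _N_STATS = 3 * (7 + 8)

    def __init__(self, dim: int = 32, seed: int = 0) -> None:
        self.dim = dim
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._proj = rng.normal(
            0.0, 1.0 / np.sqrt(self._N_STATS), size=(self._N_STATS, dim)
        )

    @property
    def encoder_id(self) -> str:
        return f"stats-rp-d{self.dim}-seed{self.seed}"

    def __call__(self, patch: np.ndarray) -> np.ndarray:
        p = np.asarray(patch, dtype=float)
        stats = []
        for ch in range(3):
            v = p[..., ch].ravel()
            stats.extend([
                v.mean(), v.std(), v.min(), v.max(),
                *np.percentile(v, [25, 50, 75]),
            ])
            hist, _ = np.histogram(v, bins=8, range=(0, 255))
            stats.extend(hist / v.size)
        return np.asarray(stats) @ self._proj


def encode_patches(
    rgb_image: np.ndarray,
    grid: PatchGrid,
    encoder,
    patient_id: str = "unknown",
    allow_empty: bool = False,
) -> PatchBag | None:
    """Encode every retained patch, one feature row per grid cell, in order.

    An empty grid raises by default; with ``allow_empty=True`` it yields
    ``None`` (a bag must hold at least one patch).
    """
    img = np.asarray(rgb_image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected a 3-channel RGB image")
    if grid.n_patches == 0:
        if allow_empty:
            return None
        raise ValueError("grid contains no patches (pass allow_empty to permit)")
    ps = grid.patch_size
    rows = []
    dim = None
    for x, y in grid.coords:
        vec = np.asarray(encoder(img[y:y + ps, x:x + ps]), dtype=float).ravel()
        if dim is None:
            dim = vec.size
        elif vec.size != dim:
            raise ValueError(
                "encoder contract violation: output length varies across patches"
            )
        rows.append(vec)
    return PatchBag(
        patient_id=patient_id,
        features=np.vstack(rows),
        coords=grid.coords.copy(),
        encoder_id=getattr(encoder, "encoder_id", type(encoder).__name__),
    )
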