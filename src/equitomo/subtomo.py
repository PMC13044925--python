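"""Tomogram normalization, interest masks, patch extraction and tiling.

Training operates on cubic subtomograms (the crop operator ``C``)
extracted at identical positions from the two half-tomograms; inference
tiles a whole volume into overlapping patches and blends the network
outputs back with a partition-of-unity window so that an identity network
reproduces the input exactly.

Coordinates are 0-based ``(z, y, x)``; crops are half-open intervals
``[corner, corner + patch)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = [
    "InterestMask",
    "PatchGrid",
    "SubtomogramPair",
    "normalize_tomogram",
    "denormalize",
    "build_interest_mask",
    "sample_patch_centers",
    "extract_pair",
    "extract_patch",
    "tile_for_inference",
    "blend_patches",
]


@dataclass
class InterestMask:
    """Binary mask of regions likely to contain structure (not just ice)."""

    mask: np.ndarray
    source: str = "auto"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)


@dataclass
class SubtomogramPair:
    """Paired cubic crops ``(y0, y1)`` plus optional clean reference."""

    y0: np.ndarray
    y1: np.ndarray
    x: np.ndarray | None = None
    center: tuple[int, int, int] | None = None


@dataclass
class PatchGrid:
    """Tiling of a volume into overlapping cubic patches for inference."""

    shape: tuple[int, int, int]
    patch: int
    corners: list[tuple[int, int, int]]
    window: np.ndarray = field(repr=False)


def normalize_tomogram(v: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Zero-mean/unit-std over the whole tomogram; returns (mean, std)."""
    v = np.asarray(v, dtype=np.float64)
    mu = float(v.mean())
    sd = float(v.std())
    if sd == 0:
        raise ValueError("tomogram has zero variance; cannot normalize")
    return (v - mu) / sd, (mu, sd)


def denormalize(v: np.ndarray, stats: tuple[float, float]) -> np.ndarray:
    mu, sd = stats
    return v * sd + mu


def build_interest_mask(
    v: np.ndarray,
    z_fraction: float = 0.6,
    density_quantile: float = 0.3,
    window: int = 9,
    user_mask: np.ndarray | None = None,
) -> InterestMask:
    """Select voxels likely to contain structure.

    Keeps a central slab along z covering ``z_fraction`` of the depth,
    intersected with voxels whose local standard deviation (cubic window)
    exceeds the ``density_quantile`` quantile of its in-slab distribution.
    A user-supplied mask bypasses the heuristic entirely.
    """
    v = np.asarray(v, dtype=np.float64)
    if user_mask is not None:
        um = np.asarray(user_mask).astype(bool)
        if um.shape != v.shape:
            raise ValueError(f"user mask shape {um.shape} != volume {v.shape}")
        return InterestMask(um, source="user-file")
    nz = v.shape[0]
    half = max(1, int(round(nz * z_fraction / 2)))
    lo, hi = max(0, nz // 2 - half), min(nz, nz // 2 + half)
    slab = np.zeros(v.shape, dtype=bool)
    slab[lo:hi] = True
    if density_quantile <= 0:
        mask = slab
    else:
        local_sq = uniform_filter(v**2, size=window)
        local_mu = uniform_filter(v, size=window)
        local_sd = np.sqrt(np.maximum(local_sq - local_mu**2, 0))
        thresh = np.quantile(local_sd[slab], density_quantile)
        mask = slab & (local_sd > thresh)
    if not mask.any():
        raise ValueError(
            "interest mask is empty; supply a manual mask (user_mask=...)"
        )
    return InterestMask(mask, source="auto")


def sample_patch_centers(
    m: InterestMask, n: int, patch: int, seed: int
) -> np.ndarray:
    """Uniform random centers over mask voxels whose patch fits inside."""
    shape = np.asarray(m.mask.shape)
    if np.any(shape < patch):
        raise ValueError(f"patch {patch} does not fit in volume {tuple(shape)}")
    lo = patch // 2
    hi = shape - (patch - patch // 2)  # center may be at most this (inclusive)
    feasible = np.zeros_like(m.mask)
    feasible[lo:hi[0] + 1, lo:hi[1] + 1, lo:hi[2] + 1] = True
    feasible &= m.mask
    idx = np.argwhere(feasible)
    if len(idx) == 0:
        raise ValueError("no feasible patch centers inside the interest mask")
    rng = np.random.default_rng(seed)
    return idx[rng.integers(len(idx), size=n)]


def extract_patch(v: np.ndarray, center, patch: int) -> np.ndarray:
    c = np.asarray(center, dtype=int)
    lo = c - patch // 2
    hi = lo + patch
    if np.any(lo < 0) or np.any(hi > np.asarray(v.shape)):
        raise ValueError(f"patch at center {tuple(c)} exceeds volume {v.shape}")
    return v[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]


def extract_pair(
    v0: np.ndarray, v1: np.ndarray, center, patch: int,
    x: np.ndarray | None = None,
) -> SubtomogramPair:
    """Crop both half-tomograms (and optionally the clean volume) at one spot."""
    if v0.shape != v1.shape:
        raise ValueError(f"half-tomograms differ in shape: {v0.shape} vs {v1.shape}")
    y0 = extract_patch(v0, center, patch)
    y1 = extract_patch(v1, center, patch)
    xc = extract_patch(x, center, patch) if x is not None else None
    return SubtomogramPair(y0, y1, xc, tuple(int(c) for c in center))


def _corners_1d(n: int, patch: int, stride: int) -> list[int]:
    if patch >= n:
        return [0]
    cs = list(range(0, n - patch + 1, stride))
    if cs[-1] != n - patch:
        cs.append(n - patch)
    return cs


def tile_for_inference(
    shape: tuple[int, int, int], patch: int, overlap: int | None = None
) -> PatchGrid:
    """Tile a volume with overlapping patches and a raised-cosine window.

    Default ``overlap`` is ``patch // 4``.  The per-patch blend window is
    separable; :func:`blend_patches` renormalizes by the accumulated
    window so that weights sum to one at every voxel.
    """
    shape = tuple(int(s) for s in shape)
    if overlap is None:
        overlap = patch // 4
    if not (0 <= overlap < patch):
        raise ValueError(f"need 0 <= overlap < patch, got overlap={overlap}")
    if any(s < patch for s in shape):
        raise ValueError(f"patch {patch} larger than volume {shape}")
    stride = patch - overlap
    corners = [
        (z, y, x)
        for z in _corners_1d(shape[0], patch, stride)
        for y in _corners_1d(shape[1], patch, stride)
        for x in _corners_1d(shape[2], patch, stride)
    ]
    # raised-cosine (Hann-like) 1D profile, strictly positive so the
    # normalized weights are well defined everywhere
    w1 = 0.5 - 0.5 * np.cos(2 * np.pi * (np.arange(patch) + 0.5) / patch)
    w1 = w1 + 1e-3
    window = w1[:, None, None] * w1[None, :, None] * w1[None, None, :]
    return PatchGrid(shape, patch, corners, window)


def blend_patches(patches: list[np.ndarray], grid: PatchGrid) -> np.ndarray:
    """Stitch processed patches back into a full volume.

    Weighted average with the grid's window; the accumulated weight field
    is strictly positive at every voxel (full coverage), so the blend is a
    partition of unity and stitching untouched patches reproduces the
    input exactly up to floating point.
    """
    if len(patches) != len(grid.corners):
        raise ValueError(f"{len(patches)} patches for {len(grid.corners)} tiles")
    acc = np.zeros(grid.shape)
    wgt = np.zeros(grid.shape)
    p = grid.patch
    for patch, (z, y, x) in zip(patches, grid.corners):
        if patch.shape != (p, p, p):
            raise ValueError(f"patch shape {patch.shape} != {(p, p, p)}")
        acc[z:z + p, y:y + p, x:x + p] += grid.window * patch
        wgt[z:z + p, y:y + p, x:x + p] += grid.window
    if np.any(wgt <= 0):
        raise RuntimeError("tiling left uncovered voxels")  # pragma: no cover
    return acc / wgt
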