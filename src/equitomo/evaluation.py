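"""Fourier shell correlation between two reconstructions.

FSC is the standard consistency metric for pairs of independently
processed half-reconstructions: the normalized complex cross-correlation
of their Fourier transforms, averaged over spherical shells of radius
|k|.  Shells are indexed by integer radius of the centered frequency
coordinates (width = 1 frequency voxel); frequencies are reported in
cycles/voxel up to Nyquist (0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FSCCurve", "fsc", "central_crop", "resolution_at_threshold"]


@dataclass
class FSCCurve:
    """Shell-indexed correlation between two volumes."""

    frequencies: np.ndarray  # shell center frequency, cycles/voxel
    correlation: np.ndarray  # Re<A,B> / (||A|| ||B||) per shell
    counts: np.ndarray       # frequency voxels per shell

    def __len__(self) -> int:
        return len(self.frequencies)


def _shell_index(shape: tuple[int, ...]) -> tuple[np.ndarray, int]:
    grids = np.meshgrid(*(np.fft.fftfreq(n) * n for n in shape), indexing="ij")
    r = np.sqrt(sum(g**2 for g in grids))
    idx = np.rint(r).astype(int)
    nshell = min(s // 2 for s in shape) + 1
    return idx, nshell


def fsc(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> FSCCurve:
    """Fourier shell correlation of two equally shaped volumes.

    An optional real-space ``mask`` is applied to both volumes before
    transforming.  Shells beyond the inscribed Nyquist sphere are
    discarded.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if mask is not None:
        if mask.shape != a.shape:
            raise ValueError("mask shape mismatch")
        a = a * mask
        b = b * mask
    A = np.fft.fftn(a)
    B = np.fft.fftn(b)
    idx, nshell = _shell_index(a.shape)
    flat = idx.ravel()
    cross = np.bincount(flat, weights=(A * np.conj(B)).real.ravel())
    pa = np.bincount(flat, weights=(np.abs(A) ** 2).ravel())
    pb = np.bincount(flat, weights=(np.abs(B) ** 2).ravel())
    counts = np.bincount(flat)
    cross, pa, pb, counts = (v[:nshell] for v in (cross, pa, pb, counts))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(pa * pb > 0, cross / np.sqrt(pa * pb), 0.0)
    n = min(a.shape)
    freqs = np.arange(nshell) / n
    return FSCCurve(freqs, corr, counts)


def central_crop(v: np.ndarray, size: int | tuple[int, int, int]) -> np.ndarray:
    """Axis-centered crop (the standard protocol crops to 256^3 before FSC)."""
    v = np.asarray(v)
    sizes = (size,) * v.ndim if np.isscalar(size) else tuple(size)
    if any(s > n for s, n in zip(sizes, v.shape)):
        raise ValueError(f"crop {sizes} larger than volume {v.shape}")
    sl = tuple(
        slice(n // 2 - s // 2, n // 2 - s // 2 + s) for s, n in zip(sizes, v.shape)
    )
    return v[sl]


def resolution_at_threshold(c: FSCCurve, t: float = 0.143) -> float:
    """First frequency where the curve drops below ``t`` (linear interp).

    Returns the Nyquist frequency if the curve never crosses.
    """
    if len(c) == 0:
        raise ValueError("empty FSC curve")
    corr, freq = c.correlation, c.frequencies
    for i in range(1, len(c)):
        if corr[i] < t:
            f0, f1 = freq[i - 1], freq[i]
            c0, c1 = corr[i - 1], corr[i]
            if c0 == c1:
                return float(f1)
            w = (c0 - t) / (c0 - c1)
            return float(f0 + w * (f1 - f0))
    return float(freq[-1])
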