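"""Missing-wedge masks and the Fourier-domain corruption projector.

A tilt series acquired over a limited angular range leaves a double wedge
of 3D Fourier space unmeasured (the *missing wedge*).  The corruption
operator ``A`` is the orthogonal projector that zeroes all Fourier
components inside that wedge: ``A(v) = F^+ (m ⊙ F v)`` with ``m`` a binary
mask.  The rotated projector ``A_g = R_g A R_g^{-1}`` applies the same
wedge in the orientation induced by a group element ``g``; because the
group elements are signed permutations, ``A_g`` is realized exactly by
index-remapping the mask in frequency space.

Conventions
-----------
* Arrays are ``(z, y, x)``; the tilt axis is ``y``; the beam at zero tilt
  runs along ``z``, so the wedge is a 2D region of the ``(k_x, k_z)``
  plane extruded along ``k_y`` and centered on the ``k_z`` axis.
* Masks are stored in ``numpy.fft`` wrap-around layout (zero frequency at
  index 0).  Angle tests use the signed centered frequencies from
  ``np.fft.fftfreq``.
* The mask is hard-edged (binary) by default — the operator-theoretic
  orthogonal projection.  A cosine rolloff of configurable width is
  available (``soft_edge_deg``) but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import GroupElement, apply_transform, inverse

__all__ = [
    "TiltScheme",
    "WedgeMask",
    "make_wedge_mask",
    "apply_wedge",
    "rotate_mask",
    "apply_rotated_wedge",
]


@dataclass(frozen=True)
class TiltScheme:
    """Angular sampling of a tilt series (degrees, tilt axis = y).

    ``theta_min``/``theta_max`` bound the covered interval; ``increment``
    is the step between successive tilts.
    """

    theta_min: float = -60.0
    theta_max: float = 60.0
    increment: float = 3.0

    def __post_init__(self) -> None:
        if not (-90.0 <= self.theta_min < self.theta_max <= 90.0):
            raise ValueError(
                f"require -90 <= theta_min < theta_max <= 90, got "
                f"[{self.theta_min}, {self.theta_max}]"
            )
        if self.increment <= 0:
            raise ValueError(f"increment must be > 0, got {self.increment}")
        if len(self.angles) == 0:
            raise ValueError("tilt scheme implies an empty angle list")

    @property
    def angles(self) -> np.ndarray:
        """The implied tilt angles, inclusive of both endpoints."""
        n = int(np.floor((self.theta_max - self.theta_min) / self.increment + 1e-9)) + 1
        return self.theta_min + self.increment * np.arange(n)

    @property
    def full_range(self) -> bool:
        return self.theta_min <= -90.0 + 1e-12 and self.theta_max >= 90.0 - 1e-12


@dataclass(frozen=True)
class WedgeMask:
    """Binary Fourier-space support of the observed region.

    ``mask`` is 1 where a frequency is measured and 0 inside the missing
    wedge, in wrap-around FFT layout.
    """

    shape: tuple[int, int, int]
    mask: np.ndarray = field(repr=False)
    scheme: TiltScheme

    @property
    def missing_fraction(self) -> float:
        return float(1.0 - self.mask.mean())


def _observed(kx: np.ndarray, kz: np.ndarray, scheme: TiltScheme,
              soft_edge_deg: float = 0.0) -> np.ndarray:
    """Predicate (or soft weight) for a frequency with components kx, kz."""
    # Angle of (kx, kz) from the kx axis; Hermitian symmetrization means a
    # frequency is observed if either it or its negation lies in the
    # covered interval.
    ang = np.degrees(np.arctan2(kz, kx))
    lo, hi = scheme.theta_min, scheme.theta_max

    def inside(a: np.ndarray) -> np.ndarray:
        return (a >= lo) & (a <= hi)

    hit = inside(ang) | inside(np.where(ang > 0, ang - 180.0, ang + 180.0))
    if soft_edge_deg <= 0:
        w = hit.astype(np.float32)
    else:
        # distance (deg) to the covered set, cosine rolloff over the band
        d0 = np.minimum(np.abs(ang - lo), np.abs(ang - hi))
        angm = np.where(ang > 0, ang - 180.0, ang + 180.0)
        d1 = np.minimum(np.abs(angm - lo), np.abs(angm - hi))
        dist = np.where(hit, 0.0, np.minimum(d0, d1))
        w = (0.5 * (1 + np.cos(np.pi * np.clip(dist / soft_edge_deg, 0, 1)))).astype(
            np.float32
        )
    w[(kx == 0) & (kz == 0)] = 1.0  # zero frequency always observed
    return w


def make_wedge_mask(
    shape: tuple[int, int, int],
    scheme: TiltScheme,
    soft_edge_deg: float = 0.0,
) -> WedgeMask:
    """Build the observed-region mask for a volume of the given shape."""
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s <= 0 for s in shape):
        raise ValueError(f"shape must be three positive ints, got {shape}")
    nz, ny, nx = shape
    kz = np.fft.fftfreq(nz)[:, None]
    kx = np.fft.fftfreq(nx)[None, :]
    if scheme.full_range:
        plane = np.ones((nz, nx), dtype=np.float32)
    else:
        plane = _observed(np.broadcast_to(kx, (nz, nx)),
                          np.broadcast_to(kz, (nz, nx)), scheme, soft_edge_deg)
        # Hermitian symmetry: on even-length axes the Nyquist frequency is
        # its own negation partner modulo N, so symmetrize explicitly.
        iz = (-np.arange(nz)) % nz
        ix = (-np.arange(nx)) % nx
        plane = np.maximum(plane, plane[np.ix_(iz, ix)])
    mask = np.repeat(plane[:, None, :], ny, axis=1)
    return WedgeMask(shape, mask, scheme)


def apply_wedge(v: np.ndarray, m: WedgeMask) -> np.ndarray:
    """Apply the corruption projector ``A``: zero the wedge in Fourier space.

    Returns a real volume (the imaginary residue of the inverse transform,
    at floating-point roundoff level, is discarded).
    """
    v = np.asarray(v)
    if v.shape != m.shape:
        raise ValueError(f"volume shape {v.shape} != mask shape {m.shape}")
    out = np.fft.ifftn(np.fft.fftn(v) * m.mask).real
    return out.astype(v.dtype, copy=False) if np.issubdtype(v.dtype, np.floating) else out


def rotate_mask(g: GroupElement, m: WedgeMask) -> np.ndarray:
    """Mask of ``A_g = R_g A R_g^{-1}``: ``m_g[k] = m[M^T k mod N]``.

    The phase factors introduced by rotating about the half-integer grid
    center cancel under conjugation, leaving a pure index remap of the
    mask in integer-frequency arithmetic.
    """
    nz, ny, nx = m.shape
    if not (nz == ny == nx):
        raise ValueError(f"rotated wedge requires a cubic mask, got {m.shape}")
    n = nz
    idx = np.indices((n, n, n))  # integer frequency indices (wrap layout)
    mt = g.matrix.T
    # signed frequency q = M^T k with k taken mod N on lookup
    out_idx = np.zeros_like(idx)
    for a in range(3):
        acc = np.zeros((n, n, n), dtype=np.int64)
        for b in range(3):
            if mt[a, b] != 0:
                acc = acc + int(mt[a, b]) * idx[b]
        out_idx[a] = np.mod(acc, n)
    return m.mask[out_idx[0], out_idx[1], out_idx[2]]


def apply_rotated_wedge(g: GroupElement, v: np.ndarray, m: WedgeMask) -> np.ndarray:
    """Apply ``A_g``: the wedge projector in the orientation induced by g."""
    v = np.asarray(v)
    if v.ndim != 3 or len(set(v.shape)) != 1:
        raise ValueError(f"A_g requires a cubic volume, got shape {v.shape}")
    if v.shape != m.shape:
        raise ValueError(f"volume shape {v.shape} != mask shape {m.shape}")
    mg = rotate_mask(g, m)
    out = np.fft.ifftn(np.fft.fftn(v) * mg).real
    return out.astype(v.dtype, copy=False) if np.issubdtype(v.dtype, np.floating) else out


def wedge_interior(m: WedgeMask, shells: int = 2) -> np.ndarray:
    """Boolean wedge region eroded by ``shells`` voxels (wrap layout).

    Gridding reconstruction spreads slice values over neighboring
    frequency voxels, so energy checks on FBP outputs are performed on the
    wedge interior, excluding this boundary shell.
    """
    from scipy.ndimage import binary_erosion

    wedge = np.fft.fftshift(m.mask == 0)
    if shells > 0:
        wedge = binary_erosion(wedge, iterations=shells)
    return np.fft.ifftshift(wedge)


def apply_rotated_wedge_composed(
    g: GroupElement, v: np.ndarray, m: WedgeMask
) -> np.ndarray:
    """Reference three-step form ``R_g A R_g^{-1} v`` (used for testing)."""
    return apply_transform(g, apply_wedge(apply_transform(inverse(g), v), m))
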