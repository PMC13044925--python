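"""Tilt-series simulation: projection, noise, splitting and FBP.

The acquisition model is the parallel-beam tomographic operator: the
projection at tilt ``θ`` (about the ``y`` axis) is the line integral of
the volume along the beam; by the Fourier slice theorem its 2D transform
equals the central slice of the volume's 3D transform at orientation
``θ``.  ``project`` evaluates that slice by trilinear interpolation of the
centered 3D FFT, and ``fbp`` inverts a stack of projections by gridding
each slice back into the 3D frequency volume with per-voxel weight
normalization, leaving unmeasured frequencies (the missing wedge) at zero.

Volumes are ``(z, y, x)`` ndarrays; projections are ``(y, x)``; a tilt
series stacks them as ``(angle, y, x)`` with optional unaveraged frames
``(angle, frame, y, x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import map_coordinates

from .wedge import TiltScheme

__all__ = [
    "TiltSeries",
    "NoiseModel",
    "SplitScheme",
    "project",
    "fbp",
    "add_noise",
    "make_split_pair",
    "bin_tilt_series",
]


@dataclass
class TiltSeries:
    """A stack of projections with their tilt angles.

    ``frames`` (optional) holds the unaveraged per-tilt detector frames,
    shape ``(n_angles, n_frames, ny, nx)``; ``projections`` is always the
    per-tilt image actually used downstream, shape ``(n_angles, ny, nx)``.
    ``pixel_size`` is in Angstroms.
    """

    projections: np.ndarray
    angles: np.ndarray
    frames: np.ndarray | None = None
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.projections = np.asarray(self.projections)
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if self.projections.ndim != 3:
            raise ValueError(
                f"projections must be (n_angles, ny, nx), got {self.projections.shape}"
            )
        if len(self.angles) != self.projections.shape[0]:
            raise ValueError(
                f"{self.projections.shape[0]} projections but {len(self.angles)} angles"
            )
        if self.frames is not None:
            self.frames = np.asarray(self.frames)
            if self.frames.ndim != 4 or self.frames.shape[0] != len(self.angles) or \
                    self.frames.shape[2:] != self.projections.shape[1:]:
                raise ValueError(f"bad frames shape {self.frames.shape}")

    @property
    def n_angles(self) -> int:
        return len(self.angles)


@dataclass(frozen=True)
class NoiseModel:
    """Per-pixel noise applied to projections (or frames).

    ``gaussian``: additive ``N(0, sigma^2)``.
    ``poisson-gaussian``: shot noise at ``gain`` counts per density unit on
    the non-negative shifted image, plus additive gaussian read noise.
    """

    kind: str = "gaussian"
    sigma: float = 1.0
    gain: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "poisson-gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class SplitScheme:
    """How to split one acquisition into two independent observations.

    ``dose`` mode partitions the per-tilt frames into two sets (both splits
    keep every angle); ``angle`` mode partitions the tilt angles by index
    parity (even-indexed tilts -> split 0).  ``excluded_frames`` (0-based)
    are dropped before splitting in either mode.
    """

    mode: str = "dose"
    split0: tuple[int, ...] = ()
    split1: tuple[int, ...] = ()
    excluded_frames: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("dose", "angle"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if set(self.split0) & set(self.split1):
            raise ValueError("split0 and split1 overlap")
        if (set(self.split0) | set(self.split1)) & set(self.excluded_frames):
            raise ValueError("excluded frames appear in a split")


def _centered_fft2(p: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(p)))


def _centered_ifft2(P: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(P)))


def _slice_coords(theta_deg: float, nz: int, nx: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered-index (z, x) coordinates of the Fourier slice at ``theta``.

    The slice's in-plane frequency ``u`` (the projection's x-frequency)
    maps to 3D frequency ``(u sinθ, k_y, u cosθ)``.
    """
    th = np.radians(theta_deg)
    u = np.fft.fftshift(np.fft.fftfreq(nx))  # centered frequencies
    cz = u * np.sin(th) * nz + nz // 2
    cx = u * np.cos(th) * nx + nx // 2
    return cz, cx


def _pad_zx(v: np.ndarray, os: int) -> np.ndarray:
    """Zero-pad the z and x axes by ``os`` about the N//2 center."""
    nz, ny, nx = v.shape
    out = np.zeros((os * nz, ny, os * nx), dtype=v.dtype)
    z0 = os * nz // 2 - nz // 2
    x0 = os * nx // 2 - nx // 2
    out[z0:z0 + nz, :, x0:x0 + nx] = v
    return out


def project(
    v: np.ndarray, scheme: TiltScheme, pixel_size: float = 1.0, oversample: int = 2
) -> TiltSeries:
    """Forward-project a volume over the tilt scheme (Fourier slicing).

    ``oversample`` zero-pads the z/x axes before transforming, which
    refines the frequency grid the slice is interpolated on and keeps the
    interpolation error of the trilinear gather small.
    """
    v = np.asarray(v, dtype=np.float64)
    angles = scheme.angles
    if len(angles) == 0:
        raise ValueError("tilt scheme has no angles")
    nz, ny, nx = v.shape
    vp = _pad_zx(v, oversample)
    pz, _, px = vp.shape
    V = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(vp)))
    ky = np.arange(ny, dtype=np.float64)  # y-frequency is grid-aligned
    projs = np.empty((len(angles), ny, nx))
    x0 = px // 2 - nx // 2
    for i, th in enumerate(angles):
        cz, cx = _slice_coords(th, pz, px)
        CZ = np.broadcast_to(cz[None, :], (ny, px))
        CX = np.broadcast_to(cx[None, :], (ny, px))
        CY = np.broadcast_to(ky[:, None], (ny, px))
        coords = np.stack([CZ, CY, CX])
        Pr = map_coordinates(V.real, coords, order=1, mode="grid-wrap")
        Pi = map_coordinates(V.imag, coords, order=1, mode="grid-wrap")
        full = _centered_ifft2(Pr + 1j * Pi).real  # (ny, px)
        projs[i] = full[:, x0:x0 + nx]
    return TiltSeries(projs, angles, pixel_size=pixel_size)


def fbp(t: TiltSeries, shape: tuple[int, int, int], oversample: int = 2) -> np.ndarray:
    """Reconstruct by slice insertion with weight normalization.

    Each projection's 2D FFT is spread onto its Fourier plane with
    bilinear weights in the ``(k_z, k_x)`` plane (the ``k_y`` axis is
    grid-aligned); accumulated values are divided by accumulated weights
    and frequencies never touched stay zero — the missing wedge.
    """
    if t.n_angles == 0:
        raise ValueError("empty tilt series")
    nz, ny, nx = (int(s) for s in shape)
    if t.projections.shape[1:] != (ny, nx):
        raise ValueError(
            f"projection shape {t.projections.shape[1:]} inconsistent with {shape}"
        )
    pz, px = oversample * nz, oversample * nx
    x0c = px // 2 - nx // 2
    acc = np.zeros((pz, ny, px), dtype=np.complex128)
    wgt = np.zeros((pz, 1, px))
    for i, th in enumerate(t.angles):
        proj = np.zeros((ny, px))
        proj[:, x0c:x0c + nx] = t.projections[i]
        P = _centered_fft2(proj)  # (ny, px), centered
        cz, cx = _slice_coords(th, pz, px)
        z0 = np.floor(cz).astype(int)
        x0 = np.floor(cx).astype(int)
        fz = cz - z0
        fx = cx - x0
        for dz, wz in ((0, 1 - fz), (1, fz)):
            for dx, wx in ((0, 1 - fx), (1, fx)):
                w = wz * wx  # bilinear weight per in-plane frequency
                zi = (z0 + dz) % pz
                xi = (x0 + dx) % px
                np.add.at(acc, (zi, slice(None), xi), P.T * w[:, None])
                np.add.at(wgt, (zi, slice(None), xi), w[:, None])
    V = np.where(wgt > 1e-12, acc / np.maximum(wgt, 1e-12), 0.0)
    rec = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(V))).real
    z0c = pz // 2 - nz // 2
    return rec[z0c:z0c + nz, :, x0c:x0c + nx]


def add_noise(t: TiltSeries, nm: NoiseModel) -> TiltSeries:
    """Apply the noise model independently per pixel (and per frame)."""
    rng = np.random.default_rng(nm.seed)

    def corrupt(a: np.ndarray) -> np.ndarray:
        if nm.kind == "gaussian":
            if nm.sigma == 0:
                return a.copy()
            return a + nm.sigma * rng.standard_normal(a.shape)
        # poisson-gaussian: shot noise on the non-negative shifted image
        shift = min(0.0, float(a.min()))
        lam = np.clip(nm.gain * (a - shift), 0, None)
        out = rng.poisson(lam) / nm.gain + shift
        if nm.sigma > 0:
            out = out + nm.sigma * rng.standard_normal(a.shape)
        return out

    if t.frames is not None:
        frames = corrupt(t.frames)
        projections = frames.mean(axis=1)
        return replace(t, projections=projections, frames=frames)
    return replace(t, projections=corrupt(t.projections), frames=None)


def make_split_pair(t: TiltSeries, s: SplitScheme) -> tuple[TiltSeries, TiltSeries]:
    """Split an acquisition into two observations with independent noise."""
    if s.mode == "dose":
        if t.frames is None:
            raise ValueError("dose splitting requires per-tilt frames")
        nf = t.frames.shape[1]
        keep = [i for i in range(nf) if i not in s.excluded_frames]
        if s.split0 and s.split1:
            g0, g1 = list(s.split0), list(s.split1)
        else:  # default: alternate the remaining frames
            g0, g1 = keep[0::2], keep[1::2]
        for g in (g0, g1):
            if not g or any(i >= nf or i in s.excluded_frames for i in g):
                raise ValueError(f"invalid frame assignment {g} for {nf} frames")
        a = replace(t, projections=t.frames[:, g0].mean(axis=1), frames=t.frames[:, g0])
        b = replace(t, projections=t.frames[:, g1].mean(axis=1), frames=t.frames[:, g1])
        return a, b
    # angle mode: even-indexed tilts -> split 0, odd -> split 1
    if t.frames is not None:
        nf = t.frames.shape[1]
        keep = [i for i in range(nf) if i not in s.excluded_frames]
        base = replace(t, projections=t.frames[:, keep].mean(axis=1), frames=None)
    else:
        base = t
    ev = np.arange(t.n_angles) % 2 == 0
    a = TiltSeries(base.projections[ev], base.angles[ev], pixel_size=t.pixel_size)
    b = TiltSeries(base.projections[~ev], base.angles[~ev], pixel_size=t.pixel_size)
    return a, b


def bin_tilt_series(t: TiltSeries, factor: int) -> TiltSeries:
    """Block-average projections by ``factor``; pixel size scales by ``factor``.

    E.g. binning a 2.36 Å series by 6 yields an effective 14.16 Å pixel.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    n, ny, nx = t.projections.shape
    cy, cx = (ny // factor) * factor, (nx // factor) * factor
    p = t.projections[:, :cy, :cx].reshape(n, cy // factor, factor, cx // factor, factor)
    return TiltSeries(p.mean(axis=(2, 4)), t.angles, pixel_size=t.pixel_size * factor)
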