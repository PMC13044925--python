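"""Synthetic ground-truth volumes and paired noisy observations.

Real tomograms of cellular samples contain membranes (thin curved sheets,
here spherical shells), filaments (rods) and globular particles (gaussian
blobs).  The generator places a configurable mix of these at random poses
on a flat background, producing volumes with and without local rotational
symmetry — the property the equivariance regularizer exploits.

``generate_paired_dataset`` pushes each phantom through the acquisition
model twice with independent noise seeds, yielding the two observations
``y_0, y_1`` of the same underlying signal that self-supervised training
requires, together with the clean reference ``x`` for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .simulate import NoiseModel, add_noise, fbp, project
from .wedge import TiltScheme, apply_wedge, make_wedge_mask

__all__ = [
    "PhantomSpec",
    "PairedObservation",
    "generate_phantom",
    "generate_paired_dataset",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic volume.

    Counts are drawn uniformly from the inclusive ranges; ``contrast`` is
    the peak density of an object above ``background``.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    n_shells: tuple[int, int] = (1, 2)
    n_rods: tuple[int, int] = (2, 4)
    n_blobs: tuple[int, int] = (4, 8)
    contrast: float = 1.0
    background: float = 0.0
    smooth_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape):
            raise ValueError(f"shape must be positive, got {self.shape}")
        for lo, hi in (self.n_shells, self.n_rods, self.n_blobs):
            if lo < 0 or hi < lo:
                raise ValueError("count ranges must satisfy 0 <= lo <= hi")


@dataclass
class PairedObservation:
    """Two independently corrupted observations of one clean volume."""

    y0: np.ndarray
    y1: np.ndarray
    x: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.y0.shape != self.y1.shape:
            raise ValueError(f"y0 {self.y0.shape} != y1 {self.y1.shape}")
        if self.x is not None and self.x.shape != self.y0.shape:
            raise ValueError("clean reference shape mismatch")


def _coords(shape: tuple[int, int, int]) -> np.ndarray:
    return np.stack(np.indices(shape)).astype(np.float64)


def _sample_centers(
    rng: np.random.Generator, n: int, shape: tuple[int, int, int],
    margin: float, min_dist: float,
) -> list[np.ndarray]:
    """Rejection-sample object centers with a minimum pairwise distance."""
    centers: list[np.ndarray] = []
    lo = np.full(3, margin)
    hi = np.asarray(shape) - 1 - margin
    for _ in range(2000):
        if len(centers) == n:
            break
        c = rng.uniform(lo, np.maximum(lo, hi))
        if all(np.linalg.norm(c - p) >= min_dist for p in centers):
            centers.append(c)
    return centers


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Deterministic synthetic volume for the given spec and seed."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    v = np.full(shape, float(spec.background))
    g = _coords(shape)
    nmin = min(shape)

    n_sh = int(rng.integers(spec.n_shells[0], spec.n_shells[1] + 1))
    n_rod = int(rng.integers(spec.n_rods[0], spec.n_rods[1] + 1))
    n_blob = int(rng.integers(spec.n_blobs[0], spec.n_blobs[1] + 1))

    # membranes: thin spherical shells
    for c in _sample_centers(rng, n_sh, shape, margin=nmin * 0.2, min_dist=nmin * 0.3):
        radius = rng.uniform(nmin * 0.15, nmin * 0.3)
        thick = rng.uniform(1.0, 2.0)
        r = np.sqrt(((g - c[:, None, None, None]) ** 2).sum(axis=0))
        v += spec.contrast * np.exp(-0.5 * ((r - radius) / thick) ** 2)

    # filaments: rods of finite length along a random direction
    for c in _sample_centers(rng, n_rod, shape, margin=nmin * 0.15, min_dist=2.0):
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        half = rng.uniform(nmin * 0.15, nmin * 0.4)
        radius = rng.uniform(1.0, 2.0)
        rel = g - c[:, None, None, None]
        t = np.einsum("i,i...->...", d, rel)
        perp = np.sqrt(np.maximum(((rel - t * d[:, None, None, None]) ** 2).sum(axis=0), 0))
        along = np.clip(np.abs(t) - half, 0, None)
        v += spec.contrast * np.exp(-0.5 * (perp / radius) ** 2 - 0.5 * (along / 1.5) ** 2)

    # particles: gaussian blobs, kept apart so each is a distinct maximum
    for c in _sample_centers(rng, n_blob, shape, margin=nmin * 0.12, min_dist=nmin * 0.18):
        sig = rng.uniform(nmin * 0.03, nmin * 0.06)
        r2 = ((g - c[:, None, None, None]) ** 2).sum(axis=0)
        v += spec.contrast * np.exp(-0.5 * r2 / sig**2)

    if spec.smooth_sigma > 0:
        v = gaussian_filter(v, spec.smooth_sigma)
    return v


def generate_paired_dataset(
    spec: PhantomSpec,
    scheme: TiltScheme,
    nm: NoiseModel,
    n: int = 1,
) -> list[PairedObservation]:
    """Simulate ``n`` phantoms, each observed twice with independent noise.

    For phantom ``x``: ``y_i = A(fbp(add_noise(project(x), nm_i)))`` where
    the two noise draws use seeds derived from ``nm.seed`` (different per
    phantom and per observation).  The final wedge projection ``A`` zeroes
    the residual gridding leakage inside the wedge so each observation
    satisfies the corruption model exactly.
    """
    out = []
    mask = make_wedge_mask(spec.shape, scheme)
    for j in range(n):
        pspec = PhantomSpec(**{**spec.__dict__, "seed": spec.seed + j})
        x = generate_phantom(pspec)
        t = project(x, scheme)
        ys = []
        for i in (0, 1):
            nmi = NoiseModel(nm.kind, nm.sigma, nm.gain, seed=nm.seed + 2 * j + i)
            ys.append(apply_wedge(fbp(add_noise(t, nmi), x.shape), mask))
        out.append(
            PairedObservation(
                ys[0], ys[1], x,
                provenance={
                    "scheme": scheme, "noise": nm, "phantom_seed": pspec.seed,
                },
            )
        )
    return out
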