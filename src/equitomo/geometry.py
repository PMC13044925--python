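"""Interpolation-free rotations and flips of cubic voxel grids.

The equivariance regularizer augments training patches with rotations drawn
from the finite set of volume transformations that map a cubic voxel grid
exactly onto itself: signed permutation matrices.  The proper part of this
set is the 24-element rotation group of the cube; we keep the 20 of those
that are neither the identity nor an axis-aligned 180° rotation, and pair
each with its mirror image, giving a 40-element sampling set ``G`` (20 with
determinant +1, 20 with determinant -1).

Axis convention: arrays are indexed ``(z, y, x)`` and matrices act on
coordinate column vectors in that same order.  Transforms act about the
patch center ``(N - 1) / 2``; for a signed permutation this reduces to an
axis permutation followed by axis reversals, so voxel values are moved but
never interpolated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GroupElement",
    "RotationGroup",
    "build_group",
    "apply_transform",
    "inverse",
    "compose",
]

# Mirror used to generate the improper half of the group: reversal of the
# x axis (array axis 2), i.e. diag(1, 1, -1) in (z, y, x) coordinates.
_MIRROR = np.diag([1, 1, -1]).astype(np.int64)


@dataclass(frozen=True)
class GroupElement:
    """A signed permutation of the three grid axes.

    Attributes
    ----------
    matrix : (3, 3) int ndarray
        Entries in {-1, 0, +1}; exactly one nonzero per row and column.
    is_flip : bool
        True iff ``det(matrix) == -1``.
    label : str
        Stable identifier used in logs and checkpoints.
    """

    matrix: np.ndarray = field(repr=False)
    is_flip: bool
    label: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.int64)
        if m.shape != (3, 3):
            raise ValueError(f"matrix must be 3x3, got {m.shape}")
        if not np.array_equal(m @ m.T, np.eye(3, dtype=np.int64)):
            raise ValueError("matrix is not a signed permutation (M M^T != I)")
        det = int(round(np.linalg.det(m)))
        if det not in (-1, 1):
            raise ValueError(f"determinant must be +/-1, got {det}")
        if self.is_flip != (det == -1):
            raise ValueError("is_flip inconsistent with determinant")
        object.__setattr__(self, "matrix", m)

    @property
    def det(self) -> int:
        return -1 if self.is_flip else 1

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GroupElement):
            return NotImplemented
        return np.array_equal(self.matrix, other.matrix)

    def __hash__(self) -> int:
        return hash(self.matrix.tobytes())


@dataclass(frozen=True)
class RotationGroup:
    """Ordered collection of the sampling set G (|G| = 40)."""

    elements: tuple[GroupElement, ...]

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    def __getitem__(self, i: int) -> GroupElement:
        return self.elements[i]

    def sample(self, rng: np.random.Generator) -> GroupElement:
        """Draw one element uniformly."""
        return self.elements[int(rng.integers(len(self.elements)))]


def _signed_permutations() -> list[np.ndarray]:
    """All 48 signed permutation matrices, lexicographically ordered."""
    out = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            m = np.zeros((3, 3), dtype=np.int64)
            for r, (c, s) in enumerate(zip(perm, signs)):
                m[r, c] = s
            out.append(m)
    out.sort(key=lambda m: tuple(m.ravel()))
    return out

def _axis_180(m: np.ndarray) -> bool:
    # Axis-aligned 180° rotations are the diagonal matrices with two -1s.
    return bool(np.all(m == np.diag(np.diag(m))) and np.trace(m) == -1)


def _label(m: np.ndarray) -> str:
    ax = "zyx"
    parts = []
    for r in range(3):
        c = int(np.argmax(np.abs(m[r])))
        s = "-" if m[r, c] < 0 else "+"
        parts.append(s + ax[c])
    return "".join(parts)


def build_group() -> RotationGroup:
    """Build the 40-element augmentation set.

    Returns the 24 proper rotations of the cube minus the identity and the
    three axis-aligned 180° rotations (20 elements, det +1), each followed
    by its composition with a fixed mirror (x-axis reversal), giving 20
    more elements with det -1.  Ordering is frozen: proper elements in
    lexicographic matrix order, then their mirrored partners in the same
    order.
    """
    eye = np.eye(3, dtype=np.int64)
    proper = [
        m
        for m in _signed_permutations()
        if round(np.linalg.det(m)) == 1
        and not np.array_equal(m, eye)
        and not _axis_180(m)
    ]
    assert len(proper) == 20
    elems = [GroupElement(m, False, "R" + _label(m)) for m in proper]
    elems += [
        GroupElement(m @ _MIRROR, True, "F" + _label(m @ _MIRROR)) for m in proper
    ]
    return RotationGroup(tuple(elems))


def _axes_and_flips(m: np.ndarray) -> tuple[list[int], list[int]]:
    """Decompose the index map of ``R_g`` into a transpose + flips.

    ``(R_g v)[i] = v[j]`` with ``j = M^T (i - c) + c`` (c the center); for a
    signed permutation this is ``j_a = i_{b(a)}`` (sign +1) or
    ``j_a = (N-1) - i_{b(a)}`` (sign -1), where ``b(a)`` is the nonzero
    column of row ``a`` of ``M^T``.
    """
    mt = m.T
    axes_of_output = [0, 0, 0]  # b(a) per output axis a
    flips = []
    for a in range(3):
        b = int(np.argmax(np.abs(mt[a])))
        axes_of_output[a] = b
        if mt[a, b] < 0:
            # j_a = (N-1) - i_{b(a)}: reverse the output axis where the
            # input index appears, i.e. axis b after the transpose
            flips.append(b)
    # np.transpose(v, axes) has out[i] = v[j], j_m = i_{inv_axes[m]}; we
    # need j_a = i_{b(a)}, i.e. pass axes = inverse permutation of b.
    inv = [0, 0, 0]
    for a, b in enumerate(axes_of_output):
        inv[b] = a
    return inv, flips


def apply_transform(g: GroupElement, v: np.ndarray) -> np.ndarray:
    """Apply ``R_g`` to a cubic volume by pure index permutation.

    Output voxel ``i`` equals input voxel ``g^{-1}(i)`` in coordinates
    centered on ``(N - 1) / 2``.  The multiset of voxel values is preserved
    bitwise.
    """
    v = np.asarray(v)
    if v.ndim != 3 or len(set(v.shape)) != 1:
        raise ValueError(f"apply_transform requires a cubic volume, got shape {v.shape}")
    axes, flips = _axes_and_flips(g.matrix)
    out = np.transpose(v, axes)
    if flips:
        out = np.flip(out, axis=flips)
    return np.ascontiguousarray(out)


def inverse(g: GroupElement) -> GroupElement:
    """Inverse element; for orthogonal matrices this is the transpose."""
    m = g.matrix.T
    return GroupElement(m, g.is_flip, ("F" if g.is_flip else "R") + _label(m))


def compose(a: GroupElement, b: GroupElement) -> GroupElement:
    """Element acting as ``R_a R_b`` (apply b first)."""
    m = a.matrix @ b.matrix
    flip = int(round(np.linalg.det(m))) == -1
    return GroupElement(m, flip, ("F" if flip else "R") + _label(m))
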