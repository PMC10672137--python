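"""Registered orthonormal 1D transforms and the separable 4D group transform.

A group of M' stacked L-cubes is taken to the sparse domain by four
successive 1D transforms: an orthonormal spatial transform along x, then y,
then z, and an orthonormal transform along the stacking (group) axis.  The
spatial transform is the orthonormal type-II cosine transform; the group
transform is the full-ladder orthonormal Haar transform, defined for dyadic
lengths (length 1 is the identity).  Both are registered by name so the
profile can select them; orthonormality is what makes a sigma-scaled
threshold meaningful in the coefficient domain.

The application order x, y, z, group (inverses in reverse) is fixed for
bit-reproducibility; for separable orthonormal transforms any fixed order
yields the same operator.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable

import numpy as np
import scipy.fft


@lru_cache(maxsize=None)
def dct_matrix(n: int) -> np.ndarray:
    """Orthonormal type-II DCT matrix of size n x n (rows = basis vectors)."""
    if n < 1:
        raise ValueError("transform length must be >= 1")
    return scipy.fft.dct(np.eye(n), axis=0, norm="ortho")


@lru_cache(maxsize=None)
def haar_matrix(n: int) -> np.ndarray:
    """Full-ladder orthonormal Haar matrix for dyadic n."""
    if n < 1 or n & (n - 1):
        raise ValueError(f"Haar transform length must be a power of two, got {n}")
    h = np.ones((1, 1))
    while h.shape[0] < n:
        k = h.shape[0]
        top = np.kron(h, [1.0, 1.0])
        bot = np.kron(np.eye(k), [1.0, -1.0])
        h = np.vstack([top, bot]) / np.sqrt(2.0)
    return h


@dataclass(frozen=True)
class Transform1D:
    """A named orthonormal 1D transform given by a matrix per length."""

    name: str
    matrix: Callable[[int], np.ndarray]

    def forward(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=np.float64)
        return self.matrix(v.shape[-1]) @ v

    def inverse(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=np.float64)
        return self.matrix(v.shape[-1]).T @ v


TRANSFORMS: dict[str, Transform1D] = {
    "dct": Transform1D("dct", dct_matrix),
    "haar": Transform1D("haar", haar_matrix),
}


def get_transform(name: str) -> Transform1D:
    try:
        return TRANSFORMS[name]
    except KeyError:
        raise KeyError(
            f"unknown transform {name!r}; registered: {sorted(TRANSFORMS)}"
        ) from None


def spatial_transform_1d(vector: np.ndarray, direction: str = "forward",
                         name: str = "dct") -> np.ndarray:
    """Apply the spatial 1D transform (or its inverse) to a vector."""
    t = get_transform(name)
    if direction == "forward":
        return t.forward(vector)
    if direction == "inverse":
        return t.inverse(vector)
    raise ValueError(f"direction must be 'forward' or 'inverse', got {direction!r}")


def group_transform_1d(vector: np.ndarray, direction: str = "forward",
                       name: str = "haar") -> np.ndarray:
    """Apply the group-axis 1D transform (or its inverse) to a dyadic vector."""
    return spatial_transform_1d(vector, direction, name)


def _apply_along_axis(mat: np.ndarray, arr: np.ndarray, axis: int) -> np.ndarray:
    # contract mat's columns with arr's given axis, result axis back in place
    return np.moveaxis(np.tensordot(mat, arr, axes=(1, axis)), 0, axis)


@dataclass(frozen=True)
class Transform4D:
    """The separable forward/inverse 4D transform for (M', L, L, L) stacks."""

    spatial: str = "dct"
    group: str = "haar"

    def forward(self, stack: np.ndarray) -> np.ndarray:
        stack = np.asarray(stack, dtype=np.float64)
        if stack.ndim != 4:
            raise ValueError(f"group stack must be 4D, got {stack.ndim}D")
        s = get_transform(self.spatial).matrix
        g = get_transform(self.group).matrix
        out = stack
        for axis in (1, 2, 3):  # x, y, z
            out = _apply_along_axis(s(stack.shape[axis]), out, axis)
        return _apply_along_axis(g(stack.shape[0]), out, 0)

    def inverse(self, coeffs: np.ndarray) -> np.ndarray:
        coeffs = np.asarray(coeffs, dtype=np.float64)
        if coeffs.ndim != 4:
            raise ValueError(f"coefficient array must be 4D, got {coeffs.ndim}D")
        s = get_transform(self.spatial).matrix
        g = get_transform(self.group).matrix
        out = _apply_along_axis(g(coeffs.shape[0]).T, coeffs, 0)
        for axis in (3, 2, 1):  # z, y, x
            out = _apply_along_axis(s(coeffs.shape[axis]).T, out, axis)
        return out


def forward_4d(stack: np.ndarray, spatial: str = "dct",
               group: str = "haar") -> np.ndarray:
    """Transform a group stack (M', L, L, L) into the sparse domain."""
    return Transform4D(spatial, group).forward(stack)


def inverse_4d(coeffs: np.ndarray, spatial: str = "dct",
               group: str = "haar") -> np.ndarray:
    """Exact inverse of `forward_4d`."""
    return Transform4D(spatial, group).inverse(coeffs)
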