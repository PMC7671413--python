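"""Exact geometry of natural-number lattice compositions.

A *lattice composition* is a vector of non-negative integer counts read as
compositional data: only the ratios between parts are informative, so the
points (1, 2, 3) and (100, 200, 300) are compositionally equivalent.  Closure
projects a count vector onto the simplex; the centered log-ratio (clr)
transform maps it onto the zero-sum plane.  Both maps are many-to-one on the
integer lattice: all points on the same ray from the origin collapse to a
single image.  This module provides the exact (integer gcd) machinery for
counting those collapses, the clr/ilr transforms, and the Riemann-zeta
density of lattice points visible from the origin.

Uniqueness is always decided in exact integer arithmetic via
:func:`canonical_ray`, never by comparing floating-point closures.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

from .errors import EmptyInputError, InvalidRangeError, LogDomainError, ZeroTotalError

__all__ = [
    "generate_grid",
    "closure",
    "canonical_ray",
    "count_unique_closed",
    "visible_from_origin",
    "zeta",
    "clr",
    "ilr2",
]


def _as_bounds(value, dims: int | None, name: str) -> tuple[int, ...]:
    if np.isscalar(value):
        if dims is None:
            raise InvalidRangeError(f"{name} is scalar, so dims must be given")
        return (int(value),) * dims
    bounds = tuple(int(v) for v in value)
    if dims is not None and len(bounds) != dims:
        raise InvalidRangeError(f"{name} has length {len(bounds)}, expected dims={dims}")
    return bounds


def generate_grid(lo, hi, dims: int | None = None) -> np.ndarray:
    """Return every integer point of the box ``[lo, hi]`` in lexicographic order.

    ``lo`` and ``hi`` may be scalars (with ``dims`` giving the dimension) or
    per-axis sequences.  The result is an ``(n, D)`` int64 array with
    ``n = prod(hi - lo + 1)``.
    """
    lo_t = _as_bounds(lo, dims, "lo")
    hi_t = _as_bounds(hi, dims if dims is not None else len(lo_t), "hi")
    if len(lo_t) != len(hi_t):
        raise InvalidRangeError("lo and hi must have the same dimension")
    D = len(lo_t)
    if D < 2:
        raise InvalidRangeError(f"need at least two parts, got D={D}")
    if any(h < l for l, h in zip(lo_t, hi_t)):
        raise InvalidRangeError(f"hi must be >= lo componentwise: lo={lo_t}, hi={hi_t}")
    axes = [np.arange(l, h + 1, dtype=np.int64) for l, h in zip(lo_t, hi_t)]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=-1)


def closure(x) -> np.ndarray:
    """Divide a vector (or each row of a matrix) by its total.

    The result lies on the simplex: parts are non-negative and sum to 1.
    Ratios between parts are preserved, so closure is scale-invariant.
    """
    arr = np.asarray(x, dtype=float)
    totals = arr.sum(axis=-1, keepdims=True)
    if np.any(arr < 0):
        raise ZeroTotalError("closure requires non-negative parts")
    if np.any(totals <= 0):
        raise ZeroTotalError("cannot close a vector with zero total")
    return arr / totals


def canonical_ray(point: Iterable[int]) -> tuple[int, ...]:
    """Reduce an integer point to the coprime representative of its ray.

    Two lattice points have equal canonical rays iff their closures (and
    hence their clr images) coincide — this is the exact-arithmetic
    uniqueness key used throughout the package.
    """
    coords = tuple(int(c) for c in point)
    if any(c < 0 for c in coords):
        raise ZeroTotalError("lattice points have non-negative coordinates")
    g = math.gcd(*coords)
    if g == 0:
        raise ZeroTotalError("the all-zero point lies on no ray from the origin")
    return tuple(c // g for c in coords)


def count_unique_closed(grid) -> int:
    """Number of distinct compositions after closing every point of a grid.

    Counted as the number of distinct canonical rays, in exact integer
    arithmetic.  Equal to the number of distinct clr (and ilr) images.
    """
    arr = np.asarray(grid)
    if arr.size == 0:
        raise EmptyInputError("cannot count an empty grid")
    return len({canonical_ray(row) for row in arr})


def visible_from_origin(point: Iterable[int]) -> bool:
    """True iff no other lattice point lies between ``point`` and the origin.

    A lattice point is visible from the origin exactly when its coordinates
    are coprime (gcd = 1); for random points in D dimensions the density of
    visible points is 1/zeta(D).
    """
    coords = tuple(int(c) for c in point)
    g = math.gcd(*coords)
    if g == 0:
        raise ZeroTotalError("the origin itself has no visibility status")
    return g == 1


def zeta(s: float, tol: float = 1e-9) -> float:
    """Riemann zeta function for real ``s`` > 1.

    Direct series summation accelerated with an Euler–Maclaurin tail:

        zeta(s) = sum_{n<=N} n^-s + N^(1-s)/(s-1) - N^-s/2 + s N^(-s-1)/12

    with N grown until the magnitude of the next correction term,
    s(s+1)(s+2) N^(-s-3)/720, is below ``tol``.
    """
    s = float(s)
    if s <= 1.0:
        raise ValueError(f"zeta diverges for s <= 1 (got s={s})")
    if tol <= 0:
        raise ValueError("tol must be positive")
    N = 16
    while s * (s + 1.0) * (s + 2.0) * N ** (-s - 3.0) / 720.0 > tol:
        N *= 2
    n = np.arange(1, N + 1, dtype=float)
    partial = float(np.sum(n ** (-s)))
    tail = N ** (1.0 - s) / (s - 1.0) - 0.5 * N ** (-s) + s * N ** (-s - 1.0) / 12.0
    return partial + tail


def clr(x, base: float = 10.0) -> np.ndarray:
    """Centered log-ratio transform of a positive vector (or matrix rows).

    clr(x)_j = log(x_j / g_m(x)) where g_m is the geometric mean; the output
    sums to zero and is invariant to scaling the input by any positive
    constant.  Logarithms default to base 10.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0):
        raise LogDomainError(
            "clr requires strictly positive parts; replace zeros first "
            "(see latticecoda.zeros)"
        )
    logs = np.log(arr) / np.log(base)
    return logs - logs.mean(axis=-1, keepdims=True)


_ILR1_COEF = -math.sqrt(0.5)
_ILR2_COEF = -math.sqrt(2.0 / 3.0)


def ilr2(point: Sequence[float]) -> tuple[float, float]:
    """Two isometric log-ratio coordinates for a three-part composition.

    ilr1 = -sqrt(1/2) log10(x/y),  ilr2 = -sqrt(2/3) log10(sqrt(xy)/z).

    This specific basis is the view of the clr plane along the (1, 1, 1)
    ray, so scaling (x, y, z) by any positive constant leaves the pair
    unchanged.
    """
    arr = np.asarray(point, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("ilr2 is defined for three-part compositions")
    if np.any(arr <= 0):
        raise LogDomainError("ilr2 requires strictly positive parts")
    x, y, z = arr[..., 0], arr[..., 1], arr[..., 2]
    i1 = _ILR1_COEF * np.log10(x / y)
    i2 = _ILR2_COEF * np.log10(np.sqrt(x * y) / z)
    if arr.ndim == 1:
        return float(i1), float(i2)
    return i1, i2
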