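"""Scale-down-and-round quantization of count matrices.

Count compositions are not scale-invariant: dividing (86, 75, 309) by 10
gives (8.6, 7.5, 30.9), which is off the integer lattice, and the nearest
lattice approximation (9, 8, 31) carries strictly less information than the
original.  Scaling a whole dataset down and re-rounding collapses distinct
samples onto the same lattice point — the lower the counts, the coarser the
representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["scale_round", "distinct_rows", "QuantizationSeries", "quantization_series"]


def scale_round(counts, factor: float) -> np.ndarray:
    """Divide counts by ``factor`` and round half away from zero.

    The result lies on the natural-number lattice.  Factor 1 is the
    identity on integer input.
    """
    if not factor > 0:
        raise ValueError(f"factor must be positive, got {factor}")
    arr = np.asarray(counts)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    return np.floor(arr / float(factor) + 0.5).astype(np.int64)


def distinct_rows(counts) -> int:
    """Number of unique rows of a matrix (a vector counts as one row each)."""
    arr = np.asarray(counts)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.size == 0:
        return 0
    return len(np.unique(arr, axis=0))


@dataclass(frozen=True)
class QuantizationLevel:
    scale_factor: float
    counts: np.ndarray
    n_distinct: int


@dataclass(frozen=True)
class QuantizationSeries:
    """Distinct-row counts of one matrix under increasing scale-down factors."""

    levels: tuple[QuantizationLevel, ...]

    @property
    def n_distinct(self) -> list[int]:
        return [lv.n_distinct for lv in self.levels]


def quantization_series(counts, factors: Sequence[float]) -> QuantizationSeries:
    """Quantize the *original* counts at each factor and count distinct rows.

    Each level rounds the original matrix (not the previous level), e.g.
    86 -> 9 at factor 10 and 86 -> 1 at factor 100.  n_distinct is
    non-increasing along increasing factors.
    """
    factors = [float(f) for f in factors]
    if any(f <= 0 for f in factors):
        raise ValueError("factors must be positive")
    if any(b < a for a, b in zip(factors, factors[1:])):
        raise ValueError("factors must be non-decreasing")
    levels = []
    for f in factors:
        q = scale_round(counts, f)
        levels.append(QuantizationLevel(f, q, distinct_rows(q)))
    return QuantizationSeries(tuple(levels))
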