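"""Count-distribution profiling, rarity categories and feature filtering.

Sequencing studies differ sharply in the shape of their count
distributions: transcriptomic data have few zeros and large counts, while
environmental/metagenomic surveys are inundated with zeros and a long tail
of rare taxa (the "rare biosphere").  This module provides the tools for
seeing that structure in a count matrix:

- log-like binning of counts (bins 0, 1-10, ..., 91-100, 101-200, ...,
  1001-2000, ..., widths growing tenfold at each order of magnitude);
- the six abundance/rarity categories defined by per-sample relative
  abundance against thresholds 0.01% (rare) and 1% (abundant):
  AAT always abundant, CAT conditionally abundant, ART always rare,
  CRT conditionally rare, MT moderate, CRAT conditionally rare and
  abundant;
- low-abundance feature filtering by relative abundance, maximum count or
  total count, with before/after summaries of sequences, features, zero
  cells and small-count (2-9) cells.

Matrices are oriented samples x features throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError

__all__ = [
    "CATEGORIES",
    "LogLikeBins",
    "build_bins",
    "bin_profile",
    "relative_abundance",
    "classify_taxa",
    "FilterSummary",
    "summarize_matrix",
    "filter_features",
    "category_summary",
]

CATEGORIES = ("AAT", "CAT", "ART", "CRT", "MT", "CRAT")


@dataclass(frozen=True)
class LogLikeBins:
    """Integer bins 0 | 1-10 | ... | 91-100 | 101-200 | ... | 1001-2000 | ...

    ``lowers``/``uppers`` are inclusive bounds; the first bin is exactly
    {0}; bin widths multiply by 10 at each decade boundary.
    """

    lowers: tuple[int, ...]
    uppers: tuple[int, ...]
    labels: tuple[str, ...]

    def assign(self, counts) -> np.ndarray:
        """Bin index for each entry of an integer array."""
        arr = np.asarray(counts)
        idx = np.searchsorted(np.asarray(self.uppers), arr, side="left")
        if np.any(arr > self.uppers[-1]) or np.any(arr < 0):
            raise ValueError("counts fall outside the binning range")
        return idx


def build_bins(max_count: int) -> LogLikeBins:
    """Bins covering 0..max_count with the log-like rule."""
    if max_count < 0:
        raise ValueError("max_count must be non-negative")
    lowers, uppers, labels = [0], [0], ["0"]
    width = 10
    lo = 1
    while uppers[-1] < max_count:
        hi = lo + width - 1
        lowers.append(lo)
        uppers.append(hi)
        labels.append(f"{lo}-{hi}")
        lo = hi + 1
        if hi == 10 * width:  # decade boundary: widths grow tenfold
            width *= 10
    return LogLikeBins(tuple(lowers), tuple(uppers), tuple(labels))


def bin_profile(counts, bins: LogLikeBins | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample percentage of cells per bin, plus a five-number summary.

    Returns ``(per_sample, summary)``: ``per_sample`` has one row per
    sample and one column per bin (percentages summing to 100 per row);
    ``summary`` gives min, Q1, median, Q3, max of each bin's percentage
    across samples.
    """
    arr = np.asarray(counts)
    if arr.size == 0:
        raise EmptyInputError("cannot profile an empty matrix")
    if arr.ndim != 2:
        raise ValueError("expected a samples x features matrix")
    if bins is None:
        bins = build_bins(int(arr.max()))
    n_bins = len(bins.labels)
    idx = bins.assign(arr)
    N, D = arr.shape
    per_sample = np.zeros((N, n_bins))
    for i in range(N):
        per_sample[i] = np.bincount(idx[i], minlength=n_bins) / D * 100.0
    per_df = pd.DataFrame(per_sample, columns=list(bins.labels))
    q = per_df.quantile([0.0, 0.25, 0.5, 0.75, 1.0])
    q.index = ["min", "q1", "median", "q3", "max"]
    return per_df, q.T


def relative_abundance(counts) -> np.ndarray:
    """Per-sample feature proportions (rows sum to 1); zeros stay zero."""
    arr = np.asarray(counts, dtype=float)
    totals = arr.sum(axis=-1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("every sample must have a positive total")
    return arr / totals


def classify_taxa(counts, low_pct: float = 0.01, high_pct: float = 1.0) -> np.ndarray:
    """Assign each feature one of the six abundance/rarity categories.

    Thresholds are percentages of per-sample relative abundance (defaults
    0.01% and 1%).  Predicates are evaluated in precedence order so every
    feature receives exactly one label:

    1. AAT  — p >= high in all samples;
    2. CRAT — p < low in some sample and p >= high in some sample;
    3. CAT  — p >= low in all samples and p >= high in some sample;
    4. ART  — p < low in all samples;
    5. MT   — low <= p < high in all samples;
    6. CRT  — everything else (always below high, sometimes below low).
    """
    p = relative_abundance(counts) * 100.0
    ge_high = p >= high_pct
    lt_low = p < low_pct
    ge_low = ~lt_low
    out = np.empty(p.shape[1], dtype=object)
    for j in range(p.shape[1]):
        if ge_high[:, j].all():
            out[j] = "AAT"
        elif lt_low[:, j].any() and ge_high[:, j].any():
            out[j] = "CRAT"
        elif ge_low[:, j].all() and ge_high[:, j].any():
            out[j] = "CAT"
        elif lt_low[:, j].all():
            out[j] = "ART"
        elif (ge_low[:, j] & ~ge_high[:, j]).all():
            out[j] = "MT"
        else:
            out[j] = "CRT"
    return out


@dataclass(frozen=True)
class FilterSummary:
    """The four bulk quantities of a count matrix, with % of a reference.

    n_sequences: total counts; n_features: number of columns;
    n_zero_cells: cells equal to 0; n_cells_2_to_9: cells with counts in
    [2, 9].  Percentages are relative to the unfiltered (or whole) matrix.
    """

    n_sequences: int
    n_features: int
    n_zero_cells: int
    n_cells_2_to_9: int
    pct_sequences: float
    pct_features: float
    pct_zero_cells: float
    pct_cells_2_to_9: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _bulk(arr: np.ndarray) -> tuple[int, int, int, int]:
    return (
        int(arr.sum()),
        int(arr.shape[1]),
        int((arr == 0).sum()),
        int(((arr >= 2) & (arr <= 9)).sum()),
    )


def _pct(part: int, whole: int) -> float:
    return 100.0 * part / whole if whole else 0.0


def summarize_matrix(counts, reference=None) -> FilterSummary:
    """FilterSummary of ``counts`` with percentages against ``reference``."""
    arr = np.asarray(counts)
    ref = arr if reference is None else np.asarray(reference)
    s, f, z, sm = _bulk(arr)
    rs, rf, rz, rsm = _bulk(ref)
    return FilterSummary(s, f, z, sm, _pct(s, rs), _pct(f, rf), _pct(z, rz), _pct(sm, rsm))


def filter_features(
    counts,
    rule: str = "rel_abundance",
    threshold: float = 1e-4,
    mode: str = "any",
) -> tuple[np.ndarray, FilterSummary]:
    """Drop low-abundance features and summarize what remains.

    Rules: ``rel_abundance`` keeps a feature whose relative abundance
    (a *proportion*, e.g. 0.0001) meets the threshold in at least one
    sample (``mode='any'``, default), in every sample (``'all'``) or on
    average (``'mean'``); ``max_count`` keeps features whose largest
    per-sample count meets the threshold; ``total_count`` uses the summed
    count.  Removing every feature is allowed and yields an empty matrix.
    """
    arr = np.asarray(counts)
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    if rule == "rel_abundance":
        p = relative_abundance(arr)
        if mode == "any":
            keep = (p >= threshold).any(axis=0)
        elif mode == "all":
            keep = (p >= threshold).all(axis=0)
        elif mode == "mean":
            keep = p.mean(axis=0) >= threshold
        else:
            raise ValueError(f"unknown mode {mode!r}")
    elif rule == "max_count":
        keep = arr.max(axis=0) >= threshold
    elif rule == "total_count":
        keep = arr.sum(axis=0) >= threshold
    else:
        raise ValueError(f"unknown rule {rule!r}")
    filtered = arr[:, keep]
    return filtered, summarize_matrix(filtered, reference=arr)


def category_summary(counts, categories: Sequence[str]) -> pd.DataFrame:
    """Per-category bulk summary (sequences, features, zeros, 2-9 cells).

    One row per category present, percentages relative to the whole
    matrix; category totals sum to the matrix totals because the
    categories partition the features.
    """
    arr = np.asarray(counts)
    cats = np.asarray(categories)
    if cats.shape[0] != arr.shape[1]:
        raise ValueError("need one category per feature")
    rows = []
    for cat in CATEGORIES:
        sel = cats == cat
        if not sel.any():
            continue
        summ = summarize_matrix(arr[:, sel], reference=arr)
        rows.append({"category": cat, **summ.as_dict()})
    return pd.DataFrame(rows)
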