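"""The lattice proportionality sweep experiment.

A line y = kx through the origin represents exact proportionality between
two parts.  On the natural-number lattice the line can only be approximated
(except at k = 1), so the proportionality statistics computed from the
lattice approximation deviate from their continuous values vlr = phi_s = 0,
rho_p = 1 — and the deviation is pure quantization error.

The experiment sweeps the slope through all positive values (angles 0–90
degrees to the x-axis, sampled at equiangular steps), restricts the
approximating points to annular radius bands (count data have finite
range), appends a constant third part z = 1 so that phi_s and rho_p are
defined, and records all three statistics per angle and band.  The curves
are piecewise constant in theory, changing only when the set of lattice
points changes.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .proportionality import clr_transform, phi_s, rho_p, vlr

__all__ = [
    "lattice_line",
    "continuous_line",
    "band_filter",
    "sweep",
    "convergence_summary",
]


def _round_half_away(v: np.ndarray) -> np.ndarray:
    # round half away from zero; for the non-negative values used here this
    # is floor(v + 0.5), matching the quantization module
    return np.floor(v + 0.5).astype(np.int64)


def lattice_line(slope: float, r_max: int) -> np.ndarray:
    """Discrete lattice approximation of the ray y = slope * x.

    Parametrized along the dominant axis so steep lines are not
    undersampled: for slope <= 1 one point per x in 1..r_max with
    y = max(1, round(slope * x)); for slope > 1 the mirror construction
    along y.  Coordinates are clamped at 1 so logarithms stay defined.
    Returns unique (x, y) pairs as an (n, 2) int array in x-order.
    """
    if not slope > 0:
        raise ValueError(f"slope must be positive, got {slope}")
    if r_max < 2:
        raise ValueError("r_max must be at least 2")
    t = np.arange(1, int(r_max) + 1, dtype=np.int64)
    if slope <= 1.0:
        x = t
        y = np.maximum(1, _round_half_away(slope * t))
    else:
        y = t
        x = np.maximum(1, _round_half_away(t / slope))
    pts = np.unique(np.stack([x, y], axis=1), axis=0)
    return pts


def continuous_line(slope: float, r_max: int) -> np.ndarray:
    """Exact (un-rounded, un-clamped) counterpart of :func:`lattice_line`.

    Serves as the continuous oracle: with these points every angle gives
    vlr = 0 exactly, isolating rounding as the sole source of error in the
    lattice curves.
    """
    if not slope > 0:
        raise ValueError(f"slope must be positive, got {slope}")
    t = np.arange(1, int(r_max) + 1, dtype=float)
    if slope <= 1.0:
        pts = np.stack([t, slope * t], axis=1)
    else:
        pts = np.stack([t / slope, t], axis=1)
    return pts


def band_filter(points: np.ndarray, r_min: float, r_max: float) -> np.ndarray:
    """Keep points with radius in the half-open annulus (r_min, r_max].

    Half-open so adjacent bands such as (1, 10], (10, 20] partition the
    plane; the radius is the Euclidean norm of the (x, y) pair only.
    """
    if r_min < 0 or not r_min < r_max:
        raise ValueError("need 0 <= r_min < r_max")
    pts = np.asarray(points, dtype=float)
    r = np.hypot(pts[:, 0], pts[:, 1])
    keep = (r > r_min) & (r <= r_max)
    return np.asarray(points)[keep]


def _band_label(band: tuple[float, float]) -> str:
    lo, hi = band
    return f"{lo:g}-{hi:g}"


def sweep(
    bands: Sequence[tuple[float, float]] = ((1, 10), (10, 20), (20, 30)),
    n_steps: int = 900,
    delta: float = 0.05,
    base: float = 10.0,
    quantized: bool = True,
) -> pd.DataFrame:
    """Trace vlr, phi_s and rho_p across angles for each radius band.

    Angles are ``n_steps`` equiangular samples from (0 + delta) to
    (90 - delta) degrees; at each angle the slope is tan(angle), the line
    approximation is built out to the largest band radius, filtered per
    band, and a constant third part z = 1 is appended before computing the
    statistics with the points as observations.  Bands with fewer than two
    points keep their row with NaN statistics so curves retain their
    x-axis.  ``quantized=False`` substitutes the exact continuous points
    (the oracle).
    """
    if not 0 < delta < 45:
        raise ValueError("delta must lie strictly between 0 and 45 degrees")
    if n_steps < 2:
        raise ValueError("n_steps must be at least 2")
    bands = [(float(lo), float(hi)) for lo, hi in bands]
    r_build = int(math.ceil(max(hi for _, hi in bands)))
    angles = np.linspace(delta, 90.0 - delta, n_steps)
    rows = []
    for theta in angles:
        slope = math.tan(math.radians(theta))
        pts = (
            lattice_line(slope, r_build)
            if quantized
            else continuous_line(slope, r_build)
        )
        for band in bands:
            sub = band_filter(pts, band[0], band[1])
            n = len(sub)
            if n < 2:
                v = p = r = float("nan")
            else:
                table = np.column_stack([sub, np.ones(n)])
                v = vlr(table[:, 0], table[:, 1], base=base)
                C = clr_transform(table, base=base)
                p = phi_s(C, 0, 1)
                r = rho_p(C, 0, 1)
            rows.append(
                {
                    "angle_deg": float(theta),
                    "band": _band_label(band),
                    "n_points": n,
                    "vlr": v,
                    "phi_s": p,
                    "rho_p": r,
                }
            )
    return pd.DataFrame(rows)


def convergence_summary(curve: pd.DataFrame) -> pd.DataFrame:
    """Per-band summary of how far a sweep curve sits from proportionality.

    Reports mean and max of vlr and of (1 - rho_p) over the defined angles,
    plus the number of angles with undefined statistics.  As the band
    radius grows the summaries shrink toward 0 — the statistics approach
    their continuous-composition values.
    """
    if curve.empty:
        raise ValueError("cannot summarize an empty sweep curve")
    out = []
    for band, grp in curve.groupby("band", sort=False):
        defined = grp.dropna(subset=["vlr", "rho_p"])
        n_undef = len(grp) - len(defined)
        if defined.empty:
            out.append(
                {
                    "band": band,
                    "mean_vlr": float("nan"),
                    "max_vlr": float("nan"),
                    "mean_one_minus_rho": float("nan"),
                    "max_one_minus_rho": float("nan"),
                    "n_undefined": n_undef,
                }
            )
            continue
        one_minus_rho = 1.0 - defined["rho_p"]
        out.append(
            {
                "band": band,
                "mean_vlr": float(defined["vlr"].mean()),
                "max_vlr": float(defined["vlr"].max()),
                "mean_one_minus_rho": float(one_minus_rho.mean()),
                "max_one_minus_rho": float(one_minus_rho.max()),
                "n_undefined": n_undef,
            }
        )
    return pd.DataFrame(out)
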