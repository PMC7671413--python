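"""Proportionality statistics for compositional columns.

Pearson correlation is invalid on relative data; *proportionality* is the
compositionally sound notion of pairwise association.  Three statistics are
provided, all computed over the N observations (rows) of an N x D table:

- ``vlr``   — variance of log-ratios, var_i(log(x_ij / x_ik)); zero iff the
  two parts are exactly proportional, but unscaled and hard to interpret.
- ``phi_s`` — vlr scaled by var_i(c_ij + c_ik) of the clr columns; a
  distance from proportionality on [0, inf).
- ``rho_p`` — (1 - phi_s)/(1 + phi_s), a correlation-like measure with
  range (-1, 1]; equals 1 iff phi_s = 0.

phi_s and rho_p depend on the clr transform of the *full* table, so unlike
vlr they are not subcompositionally coherent.  They are undefined for
two-part tables (clr rows are (c, -c), making the denominator identically
zero) and degenerate denominators are reported as NaN rather than raised,
so that sweep curves can record gaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, LogDomainError, TwoPartCompositionError
from .geometry import clr

__all__ = [
    "ProportionalityResult",
    "clr_transform",
    "vlr",
    "phi_s",
    "rho_p",
    "proportionality",
    "pairwise_matrix",
]


def _check_positive_columns(*cols):
    for col in cols:
        if np.any(np.asarray(col) <= 0):
            raise LogDomainError("proportionality statistics need positive entries")


def _var(x: np.ndarray) -> float:
    # sample variance (N-1); the choice cancels in phi_s and rho_p
    return float(np.var(x, ddof=1))


def clr_transform(X, base: float = 10.0) -> np.ndarray:
    """Row-wise clr transform of an N x D table of positive entries."""
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected an N x D matrix")
    return clr(arr, base=base)


def vlr(col_j, col_k, base: float = 10.0) -> float:
    """Variance of log-ratios of two positive columns.

    Scale-invariant: per-row rescaling of the whole composition cancels in
    the ratio, and vlr(j, k) = var_i(c_ij - c_ik) for clr columns.
    """
    xj = np.asarray(col_j, dtype=float)
    xk = np.asarray(col_k, dtype=float)
    if xj.shape != xk.shape or xj.ndim != 1:
        raise ValueError("columns must be one-dimensional and equal-length")
    if xj.size < 2:
        raise InsufficientDataError("vlr needs at least two observations")
    _check_positive_columns(xj, xk)
    return _var(np.log(xj / xk) / np.log(base))


def phi_s(C: np.ndarray, j: int, k: int) -> float:
    """phi_s of clr columns j and k: var(c_j - c_k) / var(c_j + c_k).

    ``C`` is the full N x D clr matrix.  Raises for two-part tables; a
    degenerate (zero) denominator yields NaN.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2:
        raise ValueError("C must be the full N x D clr matrix")
    if C.shape[1] == 2:
        raise TwoPartCompositionError(
            "phi_s is undefined for two-part compositions: c_i1 + c_i2 = 0"
        )
    if C.shape[0] < 2:
        raise InsufficientDataError("phi_s needs at least two observations")
    num = _var(C[:, j] - C[:, k])
    den = _var(C[:, j] + C[:, k])
    if den == 0.0:
        return float("nan")
    return num / den


def rho_p(C: np.ndarray, j: int, k: int) -> float:
    """rho_p of clr columns j and k: (1 - phi_s)/(1 + phi_s), in (-1, 1]."""
    p = phi_s(C, j, k)
    return (1.0 - p) / (1.0 + p)


@dataclass(frozen=True)
class ProportionalityResult:
    """The three statistics for one pair of parts; NaN marks undefined."""

    vlr: float
    phi_s: float
    rho_p: float


def proportionality(X, j: int, k: int, base: float = 10.0) -> ProportionalityResult:
    """All three statistics for columns j, k of a positive N x D table."""
    arr = np.asarray(X, dtype=float)
    v = vlr(arr[:, j], arr[:, k], base=base)
    C = clr_transform(arr, base=base)
    p = phi_s(C, j, k)
    r = (1.0 - p) / (1.0 + p)
    return ProportionalityResult(vlr=v, phi_s=p, rho_p=r)


def pairwise_matrix(X, statistic: str = "vlr", base: float = 10.0) -> np.ndarray:
    """D x D matrix of a proportionality statistic over all column pairs.

    vlr and rho_p are symmetric; the diagonal is 0 for vlr/phi_s and 1 for
    rho_p.
    """
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected an N x D matrix")
    _check_positive_columns(arr)
    D = arr.shape[1]
    out = np.zeros((D, D), dtype=float)
    if statistic == "vlr":
        L = np.log(arr) / np.log(base)
        for j in range(D):
            for k in range(j + 1, D):
                out[j, k] = out[k, j] = _var(L[:, j] - L[:, k])
        return out
    if statistic in ("phi_s", "phi"):
        C = clr_transform(arr, base=base)
        for j in range(D):
            for k in range(D):
                if j != k:
                    out[j, k] = phi_s(C, j, k)
        return out
    if statistic in ("rho_p", "rho"):
        C = clr_transform(arr, base=base)
        np.fill_diagonal(out, 1.0)
        for j in range(D):
            for k in range(j + 1, D):
                out[j, k] = out[k, j] = rho_p(C, j, k)
        return out
    raise ValueError(f"unknown statistic {statistic!r}; use vlr, phi_s or rho_p")
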