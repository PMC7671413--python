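"""Zero replacement for count compositions.

Zero is the natural enemy of the logarithm, so log-ratio analysis requires
every zero count to be imputed by a small positive value first.  This
module implements the two established families of multiplicative zero
replacement plus a lattice-friendly variant:

multiplicative family (replacement independent of row total)
    ``multiplicative`` — replace each zero by ``fraction * dl`` of its
    part's detection limit; ``czm`` — count-zero multiplicative, the same
    rule with the detection limit pinned to one count (the smallest
    observable count).

Bayesian-multiplicative family (replacement varies with row total)
    A Dirichlet prior with location t (the normalized across-sample
    geometric-mean proportions, estimated from the positive entries) and
    strength s shrinks the zero cell toward its posterior expectation
    ``t_j * s_i * T_i / (T_i + s_i)`` on the count scale.  The variants
    differ only in prior strength: ``bayes_bl`` uses s = D,
    ``bayes_sq`` uses s = sqrt(T_i), ``bayes_gbm`` contributes a single
    pseudo-count in total (s = 1).

Every candidate replacement is an imputation of a value *below the
detection limit*, so candidates at or above dl are pulled back to
``fraction * dl``.  After replacement the non-zero parts of each row are
scaled down by a common factor so the row total is preserved; ratios
between non-zero parts are therefore untouched.

None of these strategies lands on the lattice of next lower magnitude
(the "tenths" lattice 0.1N): their outputs are generic reals below 1.
``lattice_friendly_replace`` is the variant that does: it rounds the
multiplicative imputation to the nearest tenth, clamped to [0.1, 0.9].

A documented caveat: parts that are zero in exactly the same rows receive
identical replacements under the multiplicative family, adding spurious
correlation between rare parts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SpecError, UnreplaceableRowError

__all__ = [
    "STRATEGIES",
    "ReplacementSpec",
    "ReplacedMatrix",
    "replace_zeros",
    "lattice_friendly_replace",
    "on_sublattice_fraction",
]

STRATEGIES = (
    "multiplicative",
    "czm",
    "bayes_gbm",
    "bayes_sq",
    "bayes_bl",
    "lattice_friendly",
)


@dataclass(frozen=True)
class ReplacementSpec:
    """Strategy name plus detection limit (count scale) and placement fraction."""

    strategy: str = "multiplicative"
    detection_limit: float | np.ndarray = 1.0
    fraction: float = 0.65

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise SpecError(f"unknown strategy {self.strategy!r}; one of {STRATEGIES}")
        if not 0.0 < self.fraction < 1.0:
            raise SpecError(f"fraction must be in (0, 1), got {self.fraction}")
        if np.any(np.asarray(self.detection_limit) <= 0):
            raise SpecError("detection limit must be positive")


@dataclass(frozen=True)
class ReplacedMatrix:
    """Positive matrix after zero replacement, with the replacement mask."""

    values: np.ndarray
    replaced_mask: np.ndarray = field(repr=False)


def _validate_counts(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected an N x D count matrix")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    zero_rows = np.where(arr.sum(axis=1) == 0)[0]
    if zero_rows.size:
        raise UnreplaceableRowError(
            f"rows {zero_rows.tolist()} are all zero and cannot be replaced"
        )
    return arr


def _prior_location(arr: np.ndarray) -> np.ndarray:
    """Normalized geometric-mean proportions per part, from positive entries.

    Parts observed in no sample fall back to the uniform location before
    normalization.
    """
    P = arr / arr.sum(axis=1, keepdims=True)
    D = arr.shape[1]
    t = np.empty(D)
    for j in range(D):
        pos = P[:, j] > 0
        t[j] = np.exp(np.log(P[pos, j]).mean()) if pos.any() else 1.0 / D
    return t / t.sum()


def _candidates(arr: np.ndarray, spec: ReplacementSpec) -> np.ndarray:
    N, D = arr.shape
    T = arr.sum(axis=1)
    dl = np.broadcast_to(np.asarray(spec.detection_limit, dtype=float), (D,))
    if spec.strategy == "multiplicative":
        return np.broadcast_to(spec.fraction * dl, (N, D)).copy(), dl
    if spec.strategy == "czm":
        # detection limit pinned to one count, the smallest observable
        return np.full((N, D), spec.fraction * 1.0), np.ones(D)
    t = _prior_location(arr)
    if spec.strategy == "bayes_bl":
        s = np.full(N, float(D))
    elif spec.strategy == "bayes_sq":
        s = np.sqrt(T)
    elif spec.strategy == "bayes_gbm":
        s = np.ones(N)
    else:  # pragma: no cover
        raise SpecError(f"strategy {spec.strategy!r} has no candidate rule")
    cand = t[None, :] * (s * T / (T + s))[:, None]
    # imputations represent values below the detection limit
    over = cand >= dl[None, :]
    cand = np.where(over, spec.fraction * dl[None, :], cand)
    return cand, dl


def replace_zeros(counts, spec: ReplacementSpec | None = None, **kwargs) -> ReplacedMatrix:
    """Replace the zeros of a count matrix according to ``spec``.

    Returns strictly positive values with the mask of replaced cells.  Row
    totals are preserved: the non-zero parts of each row are scaled by the
    common factor (T_i - sum of replacements) / T_i, which leaves ratios
    between non-zero parts unchanged.  Deterministic given the spec.
    """
    if spec is None:
        spec = ReplacementSpec(**kwargs)
    elif kwargs:
        raise TypeError("pass either a spec or keyword options, not both")
    if spec.strategy == "lattice_friendly":
        return lattice_friendly_replace(
            counts, detection_limit=spec.detection_limit, fraction=spec.fraction
        )
    arr = _validate_counts(counts)
    mask = arr == 0
    if not mask.any():
        return ReplacedMatrix(values=arr.copy(), replaced_mask=mask)
    cand, _dl = _candidates(arr, spec)
    return _apply(arr, mask, cand)


def lattice_friendly_replace(
    counts, detection_limit: float | np.ndarray = 1.0, fraction: float = 0.65
) -> ReplacedMatrix:
    """Zero replacement whose imputed values lie on the tenths lattice.

    The multiplicative imputation ``fraction * dl`` is rounded to the
    nearest tenth and clamped to [0.1, 0.9], so every replaced value
    belongs to {0.1, 0.2, ..., 0.9}.  Row totals are preserved as in
    :func:`replace_zeros`.
    """
    spec = ReplacementSpec(
        strategy="multiplicative", detection_limit=detection_limit, fraction=fraction
    )
    arr = _validate_counts(counts)
    mask = arr == 0
    if not mask.any():
        return ReplacedMatrix(values=arr.copy(), replaced_mask=mask)
    cand, _dl = _candidates(arr, spec)
    cand = np.clip(np.floor(cand * 10.0 + 0.5) / 10.0, 0.1, 0.9)
    return _apply(arr, mask, cand)


def _apply(arr: np.ndarray, mask: np.ndarray, cand: np.ndarray) -> ReplacedMatrix:
    repl_sum = np.where(mask, cand, 0.0).sum(axis=1)
    T = arr.sum(axis=1)
    if np.any(repl_sum >= T):
        raise UnreplaceableRowError(
            "replacement mass would exceed a row total; lower the detection limit"
        )
    scale = (T - repl_sum) / T
    values = arr * scale[:, None]
    values[mask] = cand[mask]
    return ReplacedMatrix(values=values, replaced_mask=mask)


def on_sublattice_fraction(replaced: ReplacedMatrix, step: float, tol: float = 1e-9) -> float:
    """Fraction of replaced entries lying on the lattice of spacing ``step``.

    An entry r is on the lattice when r/step is an integer to within
    ``tol``.  Returns 0.0 when nothing was replaced.
    """
    if not step > 0:
        raise ValueError("step must be positive")
    r = replaced.values[replaced.replaced_mask]
    if r.size == 0:
        return 0.0
    q = r / step
    return float(np.mean(np.abs(q - np.round(q)) < tol))
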