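"""Synthetic count matrices emulating the two sequencing regimes.

The package's experiments need count data with realistic distributional
structure but no external downloads.  Two regimes are emulated:

- *RNA-seq-like*: a narrow landscape of features expressed in every
  sample — log-normal abundance profile, multinomial sampling at fixed
  depth, few zeros, counts spanning 1 to beyond 1e5;
- *metagenome-like*: a cataloging survey — Zipf (power-law) abundance
  tail, per-sample presence turnover, zero fractions up to ~90%.

Also provided: the two-species Poisson cloud used by the quantization
demonstration, and a ground-truth proportional pair y = k * x * eps with
log-normal noise for parameter-recovery checks (its true vlr in base 10
is sigma_log10 squared).

All generators are bit-reproducible given a seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["two_species", "rnaseq_like", "metagenome_like", "proportional_pair"]


def two_species(
    n: int = 100, mean_x: float = 500.0, ratio: float = 0.5, seed: int | None = None
) -> np.ndarray:
    """n samples of two independent Poisson species: x ~ Poi(mean_x), y ~ Poi(ratio*mean_x)."""
    if not (mean_x > 0 and ratio > 0):
        raise ValueError("mean_x and ratio must be positive")
    rng = np.random.default_rng(seed)
    x = rng.poisson(mean_x, size=n)
    y = rng.poisson(ratio * mean_x, size=n)
    return np.stack([x, y], axis=1).astype(np.int64)


def rnaseq_like(
    n_samples: int = 16,
    n_features: int = 3000,
    depth: int = 100_000,
    dispersion: float = 1.5,
    seed: int | None = None,
) -> np.ndarray:
    """Transcriptome-style counts: log-normal profile, multinomial depth.

    Feature abundances are log-normal with log-sd ``dispersion``; each
    sample draws exactly ``depth`` reads from that profile (multinomial
    conditioning keeps per-sample totals fixed).  At the defaults the zero
    fraction stays below 10%.
    """
    if min(n_samples, n_features, depth) < 1 or dispersion <= 0:
        raise ValueError("parameters must be positive")
    rng = np.random.default_rng(seed)
    weights = rng.lognormal(mean=0.0, sigma=dispersion, size=n_features)
    p = weights / weights.sum()
    return rng.multinomial(depth, p, size=n_samples).astype(np.int64)


def metagenome_like(
    n_samples: int = 30,
    n_features: int = 10_000,
    depth: int = 65_000,
    tail_exponent: float = 1.8,
    turnover: float = 0.7,
    seed: int | None = None,
) -> np.ndarray:
    """Survey-style counts: Zipf abundance tail plus per-sample turnover.

    Base abundances follow a power law rank^(-tail_exponent) (a long tail
    of rare features); ``turnover`` is the probability that a feature is
    absent from a given sample (community membership shifts between
    environments).  Each sample then draws ``depth`` reads multinomially
    from its present features.  At the defaults the zero fraction is at
    least 75%, typically near 90%.
    """
    if min(n_samples, n_features, depth) < 1 or tail_exponent <= 0:
        raise ValueError("parameters must be positive")
    if not 0.0 <= turnover < 1.0:
        raise ValueError("turnover must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    ranks = np.arange(1, n_features + 1, dtype=float)
    base = ranks ** (-tail_exponent)
    # shuffle so rank order is not tied to column order
    rng.shuffle(base)
    out = np.zeros((n_samples, n_features), dtype=np.int64)
    for i in range(n_samples):
        present = rng.random(n_features) >= turnover
        if not present.any():
            present[rng.integers(n_features)] = True
        w = np.where(present, base, 0.0)
        out[i] = rng.multinomial(depth, w / w.sum())
    return out


def proportional_pair(
    n: int = 10_000,
    slope_k: float = 1.0,
    sigma_log10: float = 0.3,
    seed: int | None = None,
    with_third_part: bool = False,
) -> np.ndarray:
    """Exactly proportional pair with log-normal noise: y = k * x * eps.

    x is log-uniform over two decades (counts 10..1000) and
    log10(eps) ~ Normal(0, sigma_log10^2), so the true variance of
    log10-ratios between the columns is sigma_log10 squared and is
    independent of k.  With ``with_third_part`` a constant third column of
    ones is appended so phi_s and rho_p are defined.
    """
    if not (slope_k > 0 and sigma_log10 >= 0):
        raise ValueError("slope_k must be positive and sigma_log10 non-negative")
    rng = np.random.default_rng(seed)
    x = 10.0 ** rng.uniform(1.0, 3.0, size=n)
    eps = 10.0 ** rng.normal(0.0, sigma_log10, size=n)
    y = slope_k * x * eps
    cols = [x, y] + ([np.ones(n)] if with_third_part else [])
    return np.stack(cols, axis=1)
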