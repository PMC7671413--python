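import numpy as np
import pytest


def brute_force_classify(counts, low=0.01, high=1.0):
    """Independent per-feature truth-table over the six category predicates."""
    p = counts / counts.sum(axis=1, keepdims=True) * 100.0
    out = []
    for j in range(p.shape[1]):
        col = p[:, j]
        n = len(col)
        n_ge_high = int(np.sum(col >= high))
        n_lt_low = int(np.sum(col < low))
        n_ge_low = n - n_lt_low
        n_mid = int(np.sum((col >= low) & (col < high)))
        if n_ge_high == n:
            out.append("AAT")
        elif n_lt_low >= 1 and n_ge_high >= 1:
            out.append("CRAT")
        elif n_ge_low == n and n_ge_high >= 1:
            out.append("CAT")
        elif n_lt_low == n:
            out.append("ART")
        elif n_mid == n:
            out.append("MT")
        else:
            out.append("CRT")
    return np.array(out, dtype=object)


@pytest.fixture
def classify_oracle():
    return brute_force_classify


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def fig6_grid():
    """The 1100 (x, y, z) triples with x, y in 1..10 and z in 0..10."""
    from latticecoda import generate_grid

    return generate_grid((1, 1, 0), (10, 10, 10))
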