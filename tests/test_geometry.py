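"""Lattice geometry: grids, closure, rays, clr/ilr and the zeta density."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import latticecoda as lc
from latticecoda.errors import (
    EmptyInputError,
    InvalidRangeError,
    LogDomainError,
    ZeroTotalError,
)

positive_vectors = st.lists(
    st.floats(min_value=1e-3, max_value=1e6, allow_nan=False), min_size=2, max_size=8
)


class TestGenerateGrid:
    @pytest.mark.parametrize(
        "lo, hi, dims, expected_n",
        [
            (1, 10, 3, 1000),
            (1, 1, 3, 1),
            ((1, 1, 0), (10, 10, 10), None, 1100),
            (1, 4, 2, 16),
        ],
    )
    def test_sizes(self, lo, hi, dims, expected_n):
        grid = lc.generate_grid(lo, hi, dims)
        assert len(grid) == expected_n

    def test_lexicographic_order_and_degenerate_point(self):
        grid = lc.generate_grid(1, 2, 2)
        assert grid.tolist() == [[1, 1], [1, 2], [2, 1], [2, 2]]
        assert lc.generate_grid(1, 1, 3).tolist() == [[1, 1, 1]]

    def test_invalid_ranges(self):
        with pytest.raises(InvalidRangeError):
            lc.generate_grid(5, 1, 2)
        with pytest.raises(InvalidRangeError):
            lc.generate_grid(1, 10, 1)


class TestClosure:
    def test_examples(self):
        np.testing.assert_allclose(lc.closure((1, 1, 1)), [1 / 3] * 3)
        np.testing.assert_allclose(lc.closure((0, 1, 1)), [0, 0.5, 0.5])
        np.testing.assert_allclose(lc.closure((1, 2, 3)), lc.closure((100, 200, 300)))

    def test_zero_total_rejected(self):
        with pytest.raises(ZeroTotalError):
            lc.closure((0, 0, 0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(positive_vectors, st.floats(min_value=1e-6, max_value=1e6))
    def test_scale_invariance(self, v, k):
        np.testing.assert_allclose(
            lc.closure(v), lc.closure(np.asarray(v) * k), rtol=1e-9
        )


class TestCanonicalRay:
    @pytest.mark.parametrize(
        "point, expected",
        [((2, 4, 6), (1, 2, 3)), ((1, 1, 1), (1, 1, 1)),
         ((10, 10, 10), (1, 1, 1)), ((9, 8, 31), (9, 8, 31))],
    )
    def test_reduction(self, point, expected):
        assert lc.canonical_ray(point) == expected

    def test_all_zero_rejected(self):
        with pytest.raises(ZeroTotalError):
            lc.canonical_ray((0, 0, 0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=6).filter(
            lambda v: sum(v) > 0
        ),
        st.integers(min_value=1, max_value=20),
    )
    def test_scale_invariance(self, point, k):
        assert lc.canonical_ray(point) == lc.canonical_ray([k * c for c in point])


class TestUniquenessCounting:
    def test_trivial_grid(self):
        assert lc.count_unique_closed(lc.generate_grid(1, 1, 3)) == 1

    def test_small_grid_matches_fraction_oracle(self):
        # independent oracle: closure of (a, b) is the reduced fraction a/(a+b)
        grid = lc.generate_grid(1, 4, 2)
        expected = len({Fraction(int(a), int(a + b)) for a, b in grid})
        assert lc.count_unique_closed(grid) == expected

    @pytest.mark.parametrize("n, D", [(5, 2), (12, 2), (5, 3), (12, 3)])
    def test_equals_coprime_count_on_anchored_grids(self, n, D):
        # on {1..n}^D each ray's reduced representative lies in the grid,
        # so distinct rays == coprime (visible) points
        grid = lc.generate_grid(1, n, D)
        visible = sum(lc.visible_from_origin(p) for p in grid)
        assert lc.count_unique_closed(grid) == visible

    def test_distinct_count_equality_closure_clr_ilr(self):
        # closure-, clr- and ilr-uniqueness agree on a 3-part grid
        grid = lc.generate_grid(1, 6, 3)
        n_rays = lc.count_unique_closed(grid)
        clr_images = np.round(lc.clr(grid), 9)
        assert len(np.unique(clr_images, axis=0)) == n_rays
        i1, i2 = lc.ilr2(grid)
        ilr_images = np.round(np.stack([i1, i2], axis=1), 9)
        assert len(np.unique(ilr_images, axis=0)) == n_rays

    def test_empty_grid_rejected(self):
        with pytest.raises(EmptyInputError):
            lc.count_unique_closed(np.empty((0, 3), dtype=int))


class TestVisibility:
    def test_examples(self):
        assert lc.visible_from_origin((1, 1, 1))
        assert not lc.visible_from_origin((2, 4, 6))

    def test_fraction_matches_unique_count(self):
        grid = lc.generate_grid(1, 10, 3)
        frac = np.mean([lc.visible_from_origin(p) for p in grid])
        assert frac == lc.count_unique_closed(grid) / len(grid)

    def test_density_converges_to_inverse_zeta(self):
        grid = lc.generate_grid(1, 50, 3)
        frac = np.mean([lc.visible_from_origin(p) for p in grid])
        assert abs(frac - 1.0 / lc.zeta(3)) < 0.02


class TestZeta:
    def test_closed_form_at_two(self):
        assert lc.zeta(2) == pytest.approx(math.pi**2 / 6, abs=1e-9)

    def test_against_scipy_oracle(self):
        from scipy.special import zeta as scipy_zeta

        for s in (1.5, 2.0, 3.0, 4.0, 10.0):
            assert lc.zeta(s) == pytest.approx(float(scipy_zeta(s)), abs=1e-9)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            lc.zeta(1.0)
        with pytest.raises(ValueError):
            lc.zeta(0.5)


class TestClr:
    def test_constant_vectors_map_to_origin(self):
        np.testing.assert_allclose(lc.clr((10, 10, 10)), 0.0, atol=1e-12)
        np.testing.assert_allclose(lc.clr((1, 1, 1)), 0.0, atol=1e-12)

    def test_base_two_example(self):
        np.testing.assert_allclose(lc.clr((1, 2, 4), base=2), [-1, 0, 1], atol=1e-12)

    def test_rejects_zero(self):
        with pytest.raises(LogDomainError):
            lc.clr((0, 1, 1))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(positive_vectors)
    def test_sums_to_zero(self, v):
        assert abs(lc.clr(v).sum()) < 1e-9

    def test_random_vectors_sum_to_zero(self, rng):
        X = rng.uniform(0.01, 1e4, size=(1000, 5))
        assert np.all(np.abs(lc.clr(X).sum(axis=1)) < 1e-9)


class TestIlr2:
    def test_center_and_scale_invariance(self):
        assert lc.ilr2((1, 1, 1)) == pytest.approx((0.0, 0.0), abs=1e-12)
        assert lc.ilr2((10, 10, 10)) == pytest.approx((0.0, 0.0), abs=1e-12)
        assert lc.ilr2((3, 5, 7)) == pytest.approx(lc.ilr2((30, 50, 70)), abs=1e-12)

    def test_hand_computed_example(self):
        i1, i2 = lc.ilr2((10, 1, 1))
        assert i1 == pytest.approx(-math.sqrt(0.5) * math.log10(10))
        assert i2 == pytest.approx(-math.sqrt(2 / 3) * math.log10(math.sqrt(10)))

    def test_rejects_nonpositive(self):
        with pytest.raises(LogDomainError):
            lc.ilr2((0, 1, 1))
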