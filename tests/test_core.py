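"""Unit and property tests for the slope-entropy core."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from slpen import SlpEnParams, encode, slope_entropy, slpen_constant_model, symbolize

from conftest import naive_slpen

DEFAULT = SlpEnParams()


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"m": 2},
            {"m": 3.5},
            {"delta": -0.1},
            {"delta": 0.8, "gamma": 0.8},
            {"delta": 0.9, "gamma": 0.8},
            {"gamma": float("nan")},
        ],
    )
    def test_invalid_configuration_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SlpEnParams(**{"m": 6, "delta": 0.001, "gamma": 0.8, **kwargs})

    def test_derived_sizes(self):
        assert DEFAULT.n_symbols == 5
        assert DEFAULT.max_patterns == 5**5


class TestSymbolize:
    @pytest.mark.parametrize(
        "d, expected",
        [
            (1.0, 2),  # d > gamma
            (0.0, 0),
            (0.8, 1),  # d == gamma -> +1 (boundary belongs to the shallow band)
            (0.001, 0),  # d == delta -> 0
            (-0.001, 0),  # -delta boundary
            (-0.8, -1),  # d == -gamma -> -1
            (-0.5, -1),
            (-0.80001, -2),
            (0.80001, 2),
        ],
    )
    def test_threshold_boundaries(self, d, expected):
        assert symbolize(d, DEFAULT) == expected

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), -float("inf")])
    def test_non_finite_rejected(self, bad):
        with pytest.raises(ValueError):
            symbolize(bad, DEFAULT)

    @given(
        d=st.one_of(
            st.floats(-10, 10, allow_nan=False),
            st.sampled_from([0.8, -0.8, 0.001, -0.001, 0.0]),
        ),
        delta=st.floats(0, 0.5, allow_nan=False),
        width=st.floats(1e-6, 5, allow_nan=False),
    )
    def test_five_conditions_partition_the_line(self, d, delta, width):
        """Exactly one of the five symbol conditions holds for any finite d."""
        gamma = delta + width
        conditions = [
            d > gamma,
            delta < d <= gamma,
            -delta <= d <= delta,
            -gamma <= d < -delta,
            d < -gamma,
        ]
        assert sum(conditions) == 1
        symbol = symbolize(d, SlpEnParams(m=3, delta=delta, gamma=gamma))
        assert symbol == [2, 1, 0, -1, -2][conditions.index(True)]


class TestEncode:
    def test_constant_series_single_pattern(self):
        hist = encode(np.ones(66), SlpEnParams(m=4, delta=1e-3, gamma=0.2))
        assert hist.counts == {(0, 0, 0): 63}
        assert hist.k == 1 and hist.n_sub == 63

    def test_interior_outlier_adds_m_patterns(self, outlier_series, worked_params):
        """One interior outlier turns k=1 into k=m+1: the dominant string
        plus one new string per position the outlier takes in a window."""
        hist = encode(outlier_series, worked_params)
        assert hist.k == 5
        assert hist.counts[(0, 0, 0)] == 59
        singletons = {s: c for s, c in hist.counts.items() if s != (0, 0, 0)}
        assert all(c == 1 for c in singletons.values())
        assert all(2 in s or -2 in s for s in singletons)

    def test_alternating_series_two_patterns(self):
        hist = encode([0, 1, 0, 1, 0, 1], SlpEnParams(m=3))
        assert hist.counts == {(-2, 2): 2, (2, -2): 2}

    def test_difference_orientation_is_earlier_minus_later(self):
        # rising ramp: d = x_j - x_{j+1} < 0, so symbols are negative
        hist = encode([0.0, 1.0, 2.0, 3.0], SlpEnParams(m=3))
        assert hist.counts == {(-2, -2): 2}

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            encode([1.0, 2.0], SlpEnParams(m=3))

    @pytest.mark.parametrize("bad", [[1.0, float("nan"), 2.0], [[1.0, 2.0]], [1.0]])
    def test_invalid_series_rejected(self, bad):
        with pytest.raises(ValueError):
            encode(bad, DEFAULT)


class TestSlopeEntropy:
    def test_worked_constant_example(self):
        res = slope_entropy(np.ones(66), SlpEnParams(m=4, delta=1e-3, gamma=0.2))
        assert res.value == pytest.approx(-376.57, abs=5e-3)
        assert res.k == 1

    def test_worked_outlier_example(self, outlier_series, worked_params):
        res = slope_entropy(outlier_series, worked_params)
        assert res.value == pytest.approx(-40.16, abs=5e-3)
        assert res.k == 5

    def test_two_full_bins_give_zero(self):
        # two bins with counts 2,2: p_i = 1, each term vanishes
        assert slope_entropy([0, 1, 0, 1, 0, 1], SlpEnParams(m=3)).value == 0.0

    def test_value_depends_only_on_count_multiset(self, rng):
        """Which strings own which counts is irrelevant to the value."""
        x = rng.normal(size=150)
        res = slope_entropy(x, DEFAULT)
        counts = sorted(encode(x, DEFAULT).counts.values())
        k = len(counts)
        from_multiset = -sum((c / k) * math.log2(c / k) for c in counts)
        assert res.value == pytest.approx(from_multiset, rel=1e-12)

    @given(
        data=st.lists(st.integers(-3, 3), min_size=8, max_size=200),
        m=st.integers(3, 6),
        delta=st.floats(0, 0.4),
        width=st.floats(0.1, 2.0),
    )
    def test_matches_naive_oracle(self, data, m, delta, width):
        """The vectorised pipeline equals a brute-force reference that
        materialises every subsequence and counts strings in a dict."""
        if len(data) < m:
            data = data + [0] * (m - len(data))
        gamma = delta + width
        params = SlpEnParams(m=m, delta=delta, gamma=gamma)
        ref_hist, ref_entropy = naive_slpen(data, m, delta, gamma)
        hist = encode(np.asarray(data, dtype=float), params)
        assert hist.counts == ref_hist
        res = slope_entropy(np.asarray(data, dtype=float), params)
        assert res.value == pytest.approx(ref_entropy, rel=1e-12, abs=1e-12)

    @given(
        data=st.lists(st.floats(-5, 5, allow_nan=False, allow_infinity=False),
                      min_size=10, max_size=120),
        m=st.integers(3, 7),
    )
    def test_counts_conserved_and_k_bounded(self, data, m):
        if len(data) < m:
            data = data + [0.0] * (m - len(data))
        params = SlpEnParams(m=m)
        hist = encode(np.asarray(data), params)
        assert sum(hist.counts.values()) == hist.n_sub == len(data) - (m - 1)
        assert 1 <= hist.k <= min(hist.n_sub, 5 ** (m - 1))

    @pytest.mark.parametrize("step", [-2.0, -0.05, 0.0, 0.0004, 0.3, 5.0])
    @pytest.mark.parametrize("delta,gamma", [(0.001, 0.8), (0.0, 0.1), (0.2, 2.0)])
    def test_constant_gradient_attains_lower_bound(self, step, delta, gamma):
        """Any constant-slope series has a single pattern, hence the
        exact minimum -(N-m+1)*log2(N-m+1), whatever the thresholds.

        Steps are kept away from the thresholds themselves: a gradient
        within one ulp of delta or gamma can symbol-split under exact
        (no-epsilon) boundary comparison."""
        n, m = 120, 5
        x = step * np.arange(n)
        res = slope_entropy(x, SlpEnParams(m=m, delta=delta, gamma=gamma))
        n_sub = n - m + 1
        assert res.k == 1
        assert res.value == pytest.approx(-n_sub * math.log2(n_sub), rel=1e-12)


class TestConstantModel:
    def test_reduces_to_exact_minimum_at_k1(self):
        assert slpen_constant_model(4995, 1) == pytest.approx(-4995 * math.log2(4995), rel=1e-14)

    def test_cross_checks_full_pipeline_on_outlier_series(self, outlier_series, worked_params):
        """Closed form at (n_sub=63, k=5) equals the pipeline on the series
        it models: 59 dominant matches plus 4 singletons."""
        res = slope_entropy(outlier_series, worked_params)
        assert slpen_constant_model(63, 5) == pytest.approx(res.value, rel=1e-12)

    @pytest.mark.parametrize("n_sub,k", [(10, 0), (10, 11), (0, 1), (10, -1)])
    def test_out_of_range_rejected(self, n_sub, k):
        with pytest.raises(ValueError):
            slpen_constant_model(n_sub, k)

    @given(n_sub=st.integers(2, 10_000), k=st.integers(2, 50))
    def test_adding_patterns_raises_entropy_above_minimum(self, n_sub, k):
        if k > n_sub:
            k = n_sub
        assert slpen_constant_model(n_sub, k) > slpen_constant_model(n_sub, 1) - 1e-9
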