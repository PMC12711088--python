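import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from weanest.features import (
    FEATURE_COLUMNS,
    build_feature_matrix,
    consecutive_differences,
    local_slope,
    rolling_mean3,
)
from weanest.io import IndividualSeries

# ---------------------------------------------------------------------------
# independent brute-force oracles (naive loops, no vectorization)


def diff_oracle(v):
    return [0.0] + [v[i] - v[i - 1] for i in range(1, len(v))]


def roll_oracle(v):
    out = []
    for i in range(len(v)):
        w = [v[j] for j in range(max(i - 1, 0), min(i + 2, len(v)))]
        out.append(sum(w) / len(w))
    return out


def slope_oracle(v, a, window=3):
    def ols(xs, ys):
        n = len(xs)
        mx, my = sum(xs) / n, sum(ys) / n
        den = sum((x - mx) ** 2 for x in xs)
        return 0.0 if den == 0 else sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / den

    t = len(v)
    if t < window:
        return [ols(a, v)] * t
    out = []
    for i in range(t):
        lo = min(max(i - window // 2, 0), t - window)
        out.append(ols(a[lo : lo + window], v[lo : lo + window]))
    return out


# ---------------------------------------------------------------------------


class TestConsecutiveDifferences:
    def test_hand_example(self):
        np.testing.assert_allclose(
            consecutive_differences([10.0, 9.0, 8.5]), [0.0, -1.0, -0.5]
        )

    def test_constant_sequence(self):
        np.testing.assert_allclose(consecutive_differences([5, 5, 5, 5]), np.zeros(4))

    def test_decreasing_gives_negative_entries(self):
        out = consecutive_differences([5.0, 4.0, 2.5, 1.0])
        assert np.all(out[1:] < 0)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            consecutive_differences([1.0])


class TestRollingMean3:
    def test_hand_examples(self):
        np.testing.assert_allclose(
            rolling_mean3([10, 9, 8.5]), [9.5, 9.166666666666666, 8.75]
        )
        np.testing.assert_allclose(rolling_mean3([0, 3, 0]), [1.5, 1.0, 1.5])

    def test_constant_preserved(self):
        np.testing.assert_allclose(rolling_mean3([2.5] * 6, ), np.full(6, 2.5))


class TestLocalSlope:
    def test_linear_trend_recovered_everywhere(self):
        out = local_slope([10.0, 9.0, 8.0], [0.0, 1.0, 2.0])
        np.testing.assert_allclose(out, [-1.0, -1.0, -1.0])

    def test_constant_is_flat(self):
        out = local_slope([4.0] * 5, np.arange(5.0))
        np.testing.assert_allclose(out, np.zeros(5))

    def test_irregular_spacing_closed_form(self):
        # center window over ages [0,1,3]: slope = 15/7
        out = local_slope([2.0, 2.0, 8.0], [0.0, 1.0, 3.0])
        assert out[1] == pytest.approx(15 / 7)

    def test_short_series_broadcasts_global_slope(self):
        out = local_slope([1.0, 3.0], [0.0, 1.0])
        np.testing.assert_allclose(out, [2.0, 2.0])


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(2, 20), st.integers(0, 2**31 - 1))
def test_matches_bruteforce_oracles(n, seed):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=n)
    a = np.sort(rng.uniform(0, 10, size=n))
    a += np.arange(n) * 1e-3  # guard strict monotonicity
    np.testing.assert_allclose(consecutive_differences(v), diff_oracle(list(v)), atol=1e-10)
    np.testing.assert_allclose(rolling_mean3(v), roll_oracle(list(v)), atol=1e-10)
    np.testing.assert_allclose(
        local_slope(v, a), slope_oracle(list(v), list(a)), atol=1e-10
    )


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(3, 15), st.integers(0, 2**31 - 1))
def test_linearity_and_invariance_properties(n, seed):
    rng = np.random.default_rng(seed)
    x, y = rng.normal(size=n), rng.normal(size=n)
    a = np.sort(rng.uniform(0, 5, n)) + np.arange(n) * 1e-3
    alpha, beta = 2.5, -1.25
    # differences and rolling means are linear operators
    np.testing.assert_allclose(
        consecutive_differences(alpha * x + beta * y),
        alpha * consecutive_differences(x) + beta * consecutive_differences(y),
        atol=1e-9,
    )
    np.testing.assert_allclose(
        rolling_mean3(alpha * x + beta * y),
        alpha * rolling_mean3(x) + beta * rolling_mean3(y),
        atol=1e-9,
    )
    # constant offsets vanish in differences, persist in means
    np.testing.assert_allclose(
        consecutive_differences(x + 7.0), consecutive_differences(x), atol=1e-9
    )
    np.testing.assert_allclose(rolling_mean3(x + 7.0), rolling_mean3(x) + 7.0, atol=1e-9)
    # slope: shift-invariant in values, linear in values
    np.testing.assert_allclose(local_slope(x + 3.0, a), local_slope(x, a), atol=1e-9)
    np.testing.assert_allclose(local_slope(2.0 * x, a), 2.0 * local_slope(x, a), atol=1e-9)


class TestBuildFeatureMatrix:
    def test_passthrough_and_edge_rule(self, make_series):
        s = make_series(ages=[0.5, 1.5, 2.5], d15n=[12.0, 11.0, 10.0],
                        d13c=[-18.0, -19.0, -19.5])
        fm = build_feature_matrix(s)
        assert fm.channels.shape == (3, 9)
        np.testing.assert_allclose(fm.channels[:, 0], s.d15n)
        np.testing.assert_allclose(fm.channels[:, 1], s.d13c)
        np.testing.assert_allclose(fm.channels[:, 2], s.ages)
        assert fm.channels[0, 3] == 0.0  # leading difference
        assert fm.channels[0, 4] == 0.0

    def test_gap_in_one_isotope_zeroes_only_its_channels(self, make_series):
        s = make_series(ages=[0.5, 1.5, 2.5, 3.5], d15n=[12.0, 11.0, 10.5, 10.0],
                        d13c=[-18.0, np.nan, -19.5, -19.6])
        fm = build_feature_matrix(s)
        d13c_cols = [FEATURE_COLUMNS.index(c)
                     for c in ("d13C", "delta_d13C", "roll_d13C", "slope_d13C")]
        assert np.all(fm.channels[1, d13c_cols] == 0.0)
        d15n_cols = [FEATURE_COLUMNS.index(c)
                     for c in ("d15N", "delta_d15N", "roll_d15N", "slope_d15N")]
        full = build_feature_matrix(
            make_series(ages=s.ages, d15n=s.d15n, d13c=[-18.0, -19.0, -19.5, -19.6])
        )
        np.testing.assert_allclose(fm.channels[:, d15n_cols], full.channels[:, d15n_cols])
        # d13C-derived features at present rows use present neighbours only
        expected_delta = -19.5 - (-18.0)
        assert fm.channels[2, FEATURE_COLUMNS.index("delta_d13C")] == pytest.approx(
            expected_delta
        )

    def test_output_is_always_finite(self, make_series):
        s = make_series(d13c=[np.nan, np.nan, np.nan, np.nan])
        fm = build_feature_matrix(s)
        assert np.all(np.isfinite(fm.channels))
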