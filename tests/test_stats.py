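"""GC-band normalization, regressions, discretization, ANOVA, uniformity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from nucleoamp.stats import (
    CountMatrix,
    anova_between_groups,
    broken_stick_regression,
    coverage_uniformity,
    equal_frequency_discretize,
    gc_normalize,
    length_coverage_regression,
    polynomial_gc_regression,
)


def make_matrix(counts, gc, lengths=None):
    counts = pd.DataFrame(
        np.asarray(counts, dtype=float),
        index=[f"a{i}" for i in range(len(counts))],
        columns=[f"s{j}" for j in range(np.asarray(counts).shape[1])],
    )
    gc = pd.Series(gc, index=counts.index)
    if lengths is None:
        lengths = np.full(len(counts), 150)
    return CountMatrix(counts, gc, pd.Series(lengths, index=counts.index))


def random_matrix(rng, n=40, s=5):
    counts = rng.integers(50, 2000, (n, s)).astype(float)
    gc = rng.uniform(0.22, 0.78, n)
    lengths = rng.integers(100, 200, n)
    return make_matrix(counts, gc, lengths)


class TestGCNormalize:
    def test_single_band_is_identity(self, rng):
        counts = rng.integers(10, 100, (10, 3))
        matrix = make_matrix(counts, np.full(10, 0.52))
        out = gc_normalize(matrix)
        assert np.allclose(out.counts, matrix.counts)

    def test_band_with_double_median_scaled_by_half(self):
        # band [40,45): counts {2m}; band [50,55): counts around median m
        matrix = make_matrix(
            [[200.0], [100.0], [100.0], [100.0]], [0.42, 0.52, 0.53, 0.51]
        )
        out = gc_normalize(matrix)
        assert out.counts.iloc[0, 0] == pytest.approx(100.0 * 200.0 / 200.0 * 0.5 * 2)
        # explicit: r~ = r * m / m_GC = 200 * 100 / 200 = 100
        assert out.counts.iloc[0, 0] == pytest.approx(100.0)

    def test_band_medians_equal_global_median_after_normalization(self, rng):
        matrix = random_matrix(rng)
        out = gc_normalize(matrix)
        band = np.floor(matrix.gc_fraction.to_numpy() * 100 / 5).astype(int)
        for sample in matrix.counts.columns:
            m_raw = np.median(matrix.counts[sample])
            col = out.counts[sample].to_numpy()
            for b in np.unique(band):
                assert np.median(col[band == b]) == pytest.approx(m_raw)

    def test_idempotent(self, rng):
        matrix = random_matrix(rng)
        once = gc_normalize(matrix)
        twice = gc_normalize(once)
        assert np.allclose(once.counts, twice.counts)

    def test_preserves_within_band_rank_order(self, rng):
        matrix = random_matrix(rng)
        out = gc_normalize(matrix)
        band = np.floor(matrix.gc_fraction.to_numpy() * 100 / 5).astype(int)
        for b in np.unique(band):
            raw = matrix.counts.iloc[band == b, 0].to_numpy()
            new = out.counts.iloc[band == b, 0].to_numpy()
            assert np.array_equal(np.argsort(raw), np.argsort(new))

    def test_zero_median_band_is_named_error(self):
        matrix = make_matrix([[0.0], [0.0], [50.0]], [0.31, 0.32, 0.61])
        with pytest.raises(ValueError, match=r"30%.*35%"):
            gc_normalize(matrix)


class TestRegressions:
    def test_exact_line_recovered(self):
        x = np.arange(10, dtype=float)
        fit = length_coverage_regression(x, -2 * x + 5)
        assert fit.slope == pytest.approx(-2)
        assert fit.pvalue < 1e-12

    def test_identical_lengths_rejected(self):
        with pytest.raises(ValueError):
            length_coverage_regression([150] * 5, [1, 2, 3, 4, 5])

    def test_max_length_restriction_applies(self, rng):
        x = np.r_[np.full(50, 150.0), np.full(50, 190.0)] + rng.normal(0, 3, 100)
        y = np.where(x > 170, 100 - (x - 170) * 5, 100.0) + rng.normal(0, 1, 100)
        full = length_coverage_regression(x, y)
        restricted = length_coverage_regression(x, y, max_length=170)
        assert full.slope < 0 and full.pvalue < 0.05
        assert restricted.pvalue > 0.05

    def test_broken_stick_recovers_piecewise_slopes(self, rng):
        x = rng.uniform(100, 240, 300)
        y = np.where(x <= 170, 50.0, 50.0 - 5 * (x - 170)) + rng.normal(0, 2, 300)
        segs = broken_stick_regression(x, y, breakpoint=170)
        assert segs["above"].slope == pytest.approx(-5, abs=0.5)
        assert segs["below"].pvalue > 0.01

    def test_globally_linear_data_equal_slopes(self, rng):
        x = rng.uniform(100, 240, 400)
        y = 3 * x + rng.normal(0, 1, 400)
        segs = broken_stick_regression(x, y, breakpoint=170)
        for seg in segs.values():
            assert abs(seg.slope - 3) < 3 * seg.stderr

    def test_breakpoint_at_max_is_error(self):
        x = np.array([100, 120, 140, 160.0])
        with pytest.raises(ValueError):
            broken_stick_regression(x, x, breakpoint=200)

    def test_quadratic_fit_r2_one(self):
        gc = np.linspace(0.2, 0.8, 30)
        y = -3 * gc**2 + 2 * gc + 1
        coeffs, r2 = polynomial_gc_regression(gc, y)
        assert np.allclose(coeffs, [-3, 2, 1], atol=1e-8)
        assert r2 == pytest.approx(1.0)

    def test_noise_has_low_r2(self, rng):
        gc = rng.uniform(0.2, 0.8, 500)
        _, r2 = polynomial_gc_regression(gc, rng.normal(0, 1, 500))
        assert r2 < 0.05

    def test_four_point_fit_matches_normal_equations(self, rng):
        gc = np.array([0.2, 0.4, 0.6, 0.9])
        y = rng.uniform(0, 10, 4)
        coeffs, r2 = polynomial_gc_regression(gc, y)
        design = np.vander(gc, 3)
        oracle, *_ = np.linalg.lstsq(design, y, rcond=None)
        assert np.allclose(coeffs, oracle)


class TestDiscretize:
    def test_nine_distinct_three_groups(self):
        labels = equal_frequency_discretize(np.arange(9, 0, -1), 3)
        assert sorted(np.bincount(labels)) == [3, 3, 3]
        # sorted order respected: smallest third in group 0
        values = np.arange(9, 0, -1)
        assert set(values[labels == 0]) == {1, 2, 3}

    def test_all_equal_is_error(self):
        with pytest.raises(ValueError):
            equal_frequency_discretize(np.ones(9), 3)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            equal_frequency_discretize(np.arange(5), 1)

    def test_ties_go_to_lower_group(self):
        labels = equal_frequency_discretize(np.array([1.0, 2.0, 2.0, 3.0]), 2)
        assert labels[1] == labels[2] == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 5), st.integers(10, 60))
    def test_matches_sort_oracle_on_distinct_values(self, seed, k, n):
        rng = np.random.default_rng(seed)
        values = rng.permutation(n).astype(float)  # distinct
        labels = equal_frequency_discretize(values, k)
        sizes = np.bincount(labels, minlength=k)
        assert sizes.max() - sizes.min() <= 1
        order = np.argsort(values)
        assert np.all(np.diff(labels[order]) >= 0)  # monotone in value


class TestAnova:
    def test_two_groups_f_equals_squared_t(self, rng):
        y = rng.normal(0, 1, 40)
        labels = np.repeat([0, 1], 20)
        f, p = anova_between_groups(y, labels)
        t = sps.ttest_ind(y[labels == 0], y[labels == 1], equal_var=True)
        assert f == pytest.approx(t.statistic**2)
        assert p == pytest.approx(t.pvalue)

    def test_textbook_sums_of_squares(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0], "c": [6.0, 7.0, 8.0]}
        y = np.concatenate(list(groups.values()))
        labels = np.repeat([0, 1, 2], 3)
        grand = y.mean()
        ss_between = sum(3 * (np.mean(v) - grand) ** 2 for v in groups.values())
        ss_within = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in groups.values())
        f_oracle = (ss_between / 2) / (ss_within / 6)
        f, _ = anova_between_groups(y, labels)
        assert f == pytest.approx(f_oracle)

    def test_small_group_is_error(self):
        with pytest.raises(ValueError):
            anova_between_groups(np.arange(5.0), np.array([0, 0, 0, 0, 1]))


class TestUniformity:
    def test_identical_columns_zero_cv(self):
        matrix = make_matrix(np.tile([[5.0], [9.0]], (1, 4)), [0.4, 0.6])
        assert np.allclose(coverage_uniformity(matrix), 0.0)

    def test_direct_formula(self):
        matrix = make_matrix([[100.0, 200.0]], [0.5])
        cv = coverage_uniformity(matrix)
        assert cv.iloc[0] == pytest.approx(np.sqrt(2) * 50 / 150)

    def test_matches_two_pass_oracle(self, rng):
        matrix = random_matrix(rng)
        cv = coverage_uniformity(matrix)
        for i, name in enumerate(matrix.counts.index):
            row = matrix.counts.iloc[i].to_numpy()
            assert cv[name] == pytest.approx(row.std(ddof=1) / row.mean())

    def test_single_sample_is_error(self):
        with pytest.raises(ValueError):
            coverage_uniformity(make_matrix([[5.0]], [0.5]))
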