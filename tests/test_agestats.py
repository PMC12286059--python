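"""Per-CpG regression statistics: closed forms, filters, rankings."""

import numpy as np
import pytest
from scipy import stats

from nanoage import agestats, cohort
from nanoage.io import CpGSite, SampleInfo


def matrix_from(beta, ages, mod="m"):
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    sites = [CpGSite("chr1", 10 * i) for i in range(beta.shape[0])]
    samples = [SampleInfo(f"s{j}", float(a)) for j, a in enumerate(ages)]
    cov = np.full(beta.shape, 30, dtype=np.int64)
    return cohort.BetaMatrix(mod, sites, samples, beta, cov)


class TestFit:
    def test_exact_line(self):
        (row,) = agestats.fit_age_regression(matrix_from([[0.2, 0.4, 0.6]], [1, 2, 3]))
        assert row.slope == pytest.approx(0.2)
        assert row.intercept == pytest.approx(0.0)
        assert row.r2 == pytest.approx(1.0)

    def test_constant_beta_degenerates_to_null(self):
        (row,) = agestats.fit_age_regression(matrix_from([[0.5, 0.5, 0.5, 0.5]], [1, 2, 3, 4]))
        assert (row.slope, row.r2, row.p) == (0.0, 0.0, 1.0)
        assert row.direction == "flat"

    def test_seven_age_cohort_matches_linregress(self):
        ages = [5, 13, 24, 46, 60, 75, 91]
        y = [0.80, 0.78, 0.72, 0.60, 0.52, 0.45, 0.38]
        (row,) = agestats.fit_age_regression(matrix_from([y], ages))
        ref = stats.linregress(ages, y)
        assert row.slope == pytest.approx(ref.slope, abs=1e-12)
        assert row.intercept == pytest.approx(ref.intercept, abs=1e-12)
        assert row.r2 == pytest.approx(ref.rvalue**2, abs=1e-12)
        assert row.p == pytest.approx(ref.pvalue, abs=1e-12)
        assert row.direction == "negative"

    def test_vectorized_fit_equals_per_row_ols(self, rng):
        ages = np.array([5, 13, 24, 46, 60, 75, 91], dtype=float)
        beta = rng.uniform(0, 1, size=(250, 7))
        rows = agestats.fit_age_regression(matrix_from(beta, ages))
        for i in (0, 17, 100, 249):
            ref = stats.linregress(ages, beta[i])
            assert rows[i].slope == pytest.approx(ref.slope, abs=1e-10)
            assert rows[i].p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_rows_with_missing_use_per_row_n(self):
        beta = np.array([[0.1, 0.3, 0.5, 0.7, np.nan]])
        ages = [10, 20, 30, 40, 50]
        (row,) = agestats.fit_age_regression(matrix_from(beta, ages))
        assert row.n == 4
        ref = stats.linregress(ages[:4], beta[0, :4])
        assert row.slope == pytest.approx(ref.slope, abs=1e-12)

    def test_short_rows_skipped(self):
        beta = np.array([[0.1, 0.2, np.nan, np.nan], [0.1, 0.2, 0.3, 0.4]])
        rows = agestats.fit_age_regression(matrix_from(beta, [1, 2, 3, 4]))
        assert len(rows) == 1 and rows[0].site.pos0 == 10

    def test_equal_ages_error(self):
        with pytest.raises(ValueError, match="ages"):
            agestats.fit_age_regression(matrix_from([[0.1, 0.2]], [5, 5]))

    def test_permutation_invariance(self, rng):
        ages = np.array([5, 13, 24, 46, 60, 75, 91], dtype=float)
        beta = rng.uniform(0, 1, size=(20, 7))
        perm = rng.permutation(7)
        rows_a = agestats.fit_age_regression(matrix_from(beta, ages))
        rows_b = agestats.fit_age_regression(matrix_from(beta[:, perm], ages[perm]))
        for a, b in zip(rows_a, rows_b):
            assert a.slope == pytest.approx(b.slope, abs=1e-12)
            assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_affine_rescaling_of_beta(self, rng):
        # y -> y/100 scales slope and intercept by 1/100, leaves r2 and p alone
        ages = [5, 13, 24, 46, 60, 75, 91]
        beta = rng.uniform(0, 1, size=(10, 7))
        rows_a = agestats.fit_age_regression(matrix_from(beta, ages))
        rows_b = agestats.fit_age_regression(matrix_from(beta / 100.0, ages))
        for a, b in zip(rows_a, rows_b):
            assert b.slope == pytest.approx(a.slope / 100.0, rel=1e-12)
            assert b.intercept == pytest.approx(a.intercept / 100.0, rel=1e-12)
            assert b.r2 == pytest.approx(a.r2, abs=1e-12)
            assert b.p == pytest.approx(a.p, abs=1e-12)

    def test_bh_q_is_monotone_in_p_rank(self, rng):
        ages = [5, 13, 24, 46, 60, 75, 91]
        beta = rng.uniform(0, 1, size=(50, 7))
        rows = agestats.fit_age_regression(matrix_from(beta, ages))
        ordered = sorted(rows, key=lambda r: r.p)
        qs = [r.q for r in ordered]
        assert all(a <= b + 1e-15 for a, b in zip(qs, qs[1:]))
        assert all(r.q <= 1.0 for r in rows)


class TestSlopePFromR2:
    def test_boundaries(self):
        assert agestats.slope_p_from_r2(0.0, 7) == 1.0
        assert agestats.slope_p_from_r2(1.0, 7) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            agestats.slope_p_from_r2(1.2, 7)
        with pytest.raises(ValueError):
            agestats.slope_p_from_r2(0.5, 2)

    def test_strictly_decreasing_in_r2_and_n(self):
        r2s = np.linspace(0.01, 0.99, 25)
        for n in (4, 6, 7, 12):
            ps = [agestats.slope_p_from_r2(r2, n) for r2 in r2s]
            assert all(a > b for a, b in zip(ps, ps[1:]))
        for r2 in (0.3, 0.8):
            ps = [agestats.slope_p_from_r2(r2, n) for n in range(3, 30)]
            assert all(a > b for a, b in zip(ps, ps[1:]))


class TestFiltersAndRanking:
    def _rows(self, specs):
        out = []
        for i, (slope, r2, p) in enumerate(specs):
            out.append(
                agestats.AgeRegressionRow(
                    CpGSite("chr1", 10 * i), "m", 7, slope, 0.5, r2, p, p,
                    "flat" if slope == 0 else ("positive" if slope > 0 else "negative"),
                )
            )
        return out

    def test_filter_rows_defaults(self):
        rows = self._rows([(0.01, 0.85, 0.0005), (0.01, 0.85, 0.01), (0.01, 0.5, 0.0001)])
        assert agestats.filter_rows(rows) == rows[:1]

    def test_filter_rows_identity_at_trivial_thresholds(self):
        rows = self._rows([(0.01, 0.3, 0.9), (-0.02, 0.1, 0.5)])
        assert agestats.filter_rows(rows, min_r2=0.0, max_p=1.0) == rows

    def test_top_by_slope(self):
        rows = self._rows([(0.003, 0.9, 0.01), (-0.002, 0.9, 0.01), (0.001, 0.9, 0.01)])
        assert agestats.top_by_slope(rows, 1, "positive")[0].slope == 0.003
        assert agestats.top_by_slope(rows, 1, "negative")[0].slope == -0.002
        assert len(agestats.top_by_slope(rows, 99, "positive")) == 3

    def test_top_by_slope_deterministic_under_ties(self):
        rows = self._rows([(0.005, 0.9, 0.01)] * 20)
        a = agestats.top_by_slope(rows, 5, "positive")
        b = agestats.top_by_slope(list(reversed(rows)), 5, "positive")
        assert [r.site.pos0 for r in a] == [r.site.pos0 for r in b]
        assert [r.site.pos0 for r in a] == sorted(r.site.pos0 for r in a)

    def test_direction_summary_counts(self):
        rows = self._rows(
            [(0.01, 0.9, 0.01), (0.02, 0.9, 0.01)] + [(-0.01, 0.9, 0.01)] * 4
        )
        neg, pos, flat = agestats.direction_summary(rows)
        assert neg == pytest.approx(4 / 6)
        assert pos == pytest.approx(2 / 6)
        assert flat == 0.0

    def test_direction_summary_all_flat(self):
        rows = self._rows([(0.0, 0.0, 1.0)] * 3)
        assert agestats.direction_summary(rows) == (0.0, 0.0, 1.0)

    def test_direction_summary_empty_is_error(self):
        with pytest.raises(ValueError):
            agestats.direction_summary([])

    def test_flat_epsilon_classifies_small_slopes(self):
        ages = [5, 13, 24, 46, 60, 75, 91]
        beta = np.tile(np.linspace(0.5, 0.5005, 7), (1, 1))
        (row,) = agestats.fit_age_regression(matrix_from(beta, ages), flat_epsilon=1e-3)
        assert row.direction == "flat"
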