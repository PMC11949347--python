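"""Summary statistics, outlier fences, normality, Spearman correlations."""
import itertools
import math
import statistics

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

import wingflap as wf
from wingflap.cohort import analytic_height_records, make_fixture_cohort, planted_correlation
from wingflap.stats import TABLE_PAIRS, correlation_table, spearman


class TestSummarize:
    def test_constant_vector(self):
        s = wf.summarize([51.0, 51.0, 51.0])
        assert (s.mean, s.sd, s.median) == (51.0, 0.0, 51.0)

    def test_hand_computed_sd(self):
        s = wf.summarize([1, 2, 3, 4])
        assert s.mean == 2.5
        assert s.sd == pytest.approx(math.sqrt(5.0 / 3.0), abs=1e-12)
        assert (s.q1, s.median, s.q3) == (1.75, 2.5, 3.25)

    def test_matches_reference_implementations(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            v = rng.normal(size=rng.integers(2, 40)).tolist()
            s = wf.summarize(v)
            assert s.mean == pytest.approx(statistics.fmean(v), abs=1e-12)
            assert s.sd == pytest.approx(statistics.stdev(v), abs=1e-12)
            assert s.median == pytest.approx(statistics.median(v), abs=1e-12)
            assert s.min == min(v) and s.max == max(v)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wf.summarize([])
        with pytest.raises(ValueError):
            wf.summarize([float("nan")])


class TestIqrOutliers:
    def test_hand_computed_fences(self):
        flags = wf.iqr_outliers([10, 11, 12, 13, 100])
        assert flags.tolist() == [False, False, False, False, True]

    def test_constant_vector_flags_nothing(self):
        assert not wf.iqr_outliers([5.0] * 6).any()

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            wf.iqr_outliers([1, 2, 3])

    def test_normal_cohort_rarely_flagged(self):
        # at n = 28 normal data, Tukey fences flag < 1 value on average
        rng = np.random.default_rng(8)
        counts = [wf.iqr_outliers(rng.normal(size=28)).sum() for _ in range(300)]
        assert np.mean(counts) < 1.0


class TestShapiroWilk:
    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            wf.shapiro_wilk([1.0, 2.0])

    def test_power_against_heavy_tails(self):
        # 28 draws from a Cauchy: rejected at alpha=0.05 well over half the time
        rng = np.random.default_rng(3)
        rejections = sum(
            wf.shapiro_wilk(rng.standard_cauchy(28))[1] < 0.05
            for _ in range(500))
        assert rejections / 500 > 0.5

    def test_agrees_with_normal_data(self):
        rng = np.random.default_rng(4)
        w, p = wf.shapiro_wilk(rng.normal(size=28))
        assert 0.0 <= p <= 1.0 and 0.0 < w <= 1.0


class TestSpearman:
    def test_perfect_concordance_and_discordance(self):
        up = spearman([1, 2, 3], [1, 2, 3])
        down = spearman([1, 2, 3], [3, 2, 1])
        assert up.r == pytest.approx(1.0)
        assert down.r == pytest.approx(-1.0)

    def test_matches_scipy_with_ties(self):
        # rank-Pearson oracle: scipy's rho to 1e-12, t-approx p to 1e-10
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(9, 60))
            x = rng.integers(0, 8, n).astype(float)    # heavy ties
            y = x * 0.5 + rng.normal(size=n)
            ours = spearman(x, y)
            rho, p = sps.spearmanr(x, y)
            assert ours.r == pytest.approx(rho, abs=1e-12)
            assert ours.p == pytest.approx(p, abs=1e-10)

    def test_exact_permutation_matches_enumeration(self):
        rng = np.random.default_rng(6)
        for n in (5, 6, 7):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            ours = spearman(x, y)
            rx = sps.rankdata(x)
            ry = sps.rankdata(y)
            robs = abs(np.corrcoef(rx, ry)[0, 1])
            hits = sum(
                abs(np.corrcoef(rx, perm)[0, 1]) >= robs - 1e-12
                for perm in itertools.permutations(ry))
            assert ours.p == pytest.approx(hits / math.factorial(n), abs=1e-12)

    def test_pairwise_complete_handling(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0]
        y = [2.0, 1.0, 3.0, 5.0, np.nan, 7.0, 6.0, 9.0, 8.0, 11.0]
        res = spearman(x, y)
        assert res.n == 8

    def test_constant_input_is_undefined(self):
        with pytest.warns(UserWarning, match="constant"):
            res = spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert math.isnan(res.r)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base = spearman(x, y)
        warped = spearman(np.exp(x), 2.0 * y ** 3 + 1.0)
        assert warped.r == pytest.approx(base.r, abs=1e-12)
        assert warped.p == pytest.approx(base.p, abs=1e-12)


class TestCorrelationTable:
    def _records(self, n=28, seed=0, corr=None):
        cohort = make_fixture_cohort(n, seed, corr=corr)
        return analytic_height_records(cohort, seed=seed + 1)

    def test_five_variables_give_ten_ordered_pairs(self):
        table = correlation_table(self._records())
        assert len(table) == 10
        assert [(t.var_x, t.var_y) for t in table] == TABLE_PAIRS
        assert all(t.var_x != t.var_y for t in table)
        assert all(abs(t.r) <= 1.0 and 0.0 <= t.p <= 1.0 for t in table)

    def test_planted_correlation_recovered(self):
        # Gaussian-copula cohort with rho = 0.8 planted on one pair
        corr = planted_correlation({("weight_kg", "folded_wing_cm"): 0.8})
        table = correlation_table(self._records(n=200, seed=3, corr=corr),
                                  exclude_outliers=False)
        by_pair = {(t.var_x, t.var_y): t for t in table}
        r = by_pair[("weight_kg", "folded_wing_cm")].r
        assert abs(r - 0.8) <= 0.1

    def test_outlier_excluded_pairwise(self):
        records = self._records(n=28, seed=9)
        records[5].extended_primary_cm = 80.0     # gross measurement error
        table = correlation_table(records)
        by_pair = {(t.var_x, t.var_y): t for t in table}
        assert by_pair[("weight_kg", "extended_primary_cm")].n == 27
        assert by_pair[("weight_kg", "folded_wing_cm")].n == 28

    def test_join_failure_lists_ids(self):
        records = self._records(n=6)
        bouts = [wf.BoutResult(f"hen_{i:02d}", 50.0, 0, 10, 10) for i in range(6)]
        with pytest.raises(ValueError, match="hen_00"):
            correlation_table(records, bouts)
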