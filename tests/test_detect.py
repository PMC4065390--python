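import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from birthcheck.calendar_counts import DailyCountSeries
from birthcheck.detect import (
    DetectionConfig,
    detect,
    flag_outliers,
    poisson_quantile,
    poisson_tail_prob,
)
from birthcheck.gam import BirthdateGAM, GamConfig

from conftest import make_series


def tail_oracle(n: int, lam: float) -> float:
    """Brute-force partial-sum oracle for P(K >= n), in log space."""
    if n == 0:
        return 1.0
    if lam == 0:
        return 0.0
    log_term = n * math.log(lam) - lam - math.lgamma(n + 1)
    term = math.exp(log_term)
    total = 0.0
    k = n
    while True:
        total += term
        k += 1
        term *= lam / k
        if term < 1e-25 * max(total, 1e-300) or k > n + 5000:
            break
    return min(total, 1.0)


def quantile_oracle(p: float, lam: float) -> int:
    """Linear CDF scan: smallest k with CDF(k) >= p."""
    cdf = 0.0
    term = math.exp(-lam)
    k = 0
    while True:
        cdf += term
        if cdf >= p:
            return k
        k += 1
        term *= lam / k


class TestPoissonTailProb:
    def test_zero_count_is_certain(self):
        for lam in (0.001, 1.0, 500.0):
            assert poisson_tail_prob(0, lam) == 1.0

    def test_closed_form_n1(self):
        assert poisson_tail_prob(1, 0.1) == pytest.approx(
            1 - math.exp(-0.1), abs=1e-14
        )

    def test_regression_n20_lam3(self):
        # Frozen from the brute-force summation oracle (40-digit arithmetic
        # gives 8.3144235881916988...e-11).
        oracle = tail_oracle(20, 3.0)
        assert oracle == pytest.approx(8.314423588191699e-11, rel=1e-12)
        assert poisson_tail_prob(20, 3.0) == pytest.approx(oracle, abs=1e-12)

    def test_lam_zero_convention(self):
        assert poisson_tail_prob(0, 0.0) == 1.0
        assert poisson_tail_prob(3, 0.0) == 0.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            poisson_tail_prob(-1, 1.0)
        with pytest.raises(ValueError):
            poisson_tail_prob(1, -0.5)

    def test_oracle_agreement_small_grid(self):
        for lam in (0.01, 0.5, 3.0, 20.0, 100.0):
            for n in (0, 1, 2, 5, 17, 60, 200):
                assert poisson_tail_prob(n, lam) == pytest.approx(
                    tail_oracle(n, lam), abs=1e-12
                )

    @given(
        st.integers(0, 300),
        st.floats(0.01, 300.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_n_and_lam(self, n, lam):
        assert poisson_tail_prob(n + 1, lam) <= poisson_tail_prob(n, lam)
        assert poisson_tail_prob(n, lam) <= poisson_tail_prob(n, lam * 1.1) + 1e-15


class TestPoissonQuantile:
    def test_mass_at_zero(self):
        assert poisson_quantile(0.5, 1e-12) == 0

    def test_9999th_percentile_lam5(self):
        assert poisson_quantile(0.9999, 5.0) == quantile_oracle(0.9999, 5.0)

    def test_scan_oracle_grid(self):
        for lam in (0.1, 1.0, 5.0, 30.0):
            for p in (0.01, 0.5, 0.99, 0.9999):
                assert poisson_quantile(p, lam) == quantile_oracle(p, lam)

    def test_definitional_consistency_with_tail(self):
        for lam in (0.5, 5.0, 42.0):
            p = 0.9999
            k = poisson_quantile(p, lam)
            assert poisson_tail_prob(k + 1, lam) < 1 - p

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            poisson_quantile(0.0, 5.0)
        with pytest.raises(ValueError):
            poisson_quantile(1.0, 5.0)


class TestFlagOutliers:
    def make_flat(self, counts):
        counts = np.asarray(counts, dtype=np.int64)
        return DailyCountSeries(
            pd.date_range("2000-01-01", periods=len(counts)), counts
        )

    def test_extreme_spike_rank_one(self):
        counts = np.full(50, 5)
        counts[20] = 900
        series = self.make_flat(counts)
        report = flag_outliers(series, np.full(50, 5.0))
        assert report.flags[20]
        assert report.table.loc[20, "rank"] == 1

    def test_sparse_tail_single_count_not_flagged(self):
        """P(K>=1 | 0.05) ~ 0.049 is far above c: a lone individual at a
        sparse range end is not an outlier."""
        counts = np.zeros(30, dtype=np.int64)
        counts[0] = 1
        series = self.make_flat(counts)
        report = flag_outliers(series, np.full(30, 0.05))
        assert not report.flags.any()
        assert report.table.loc[0, "tail_prob"] == pytest.approx(
            1 - math.exp(-0.05), abs=1e-12
        )

    def test_count_near_intensity_not_flagged(self):
        for lam in range(1, 51):
            assert poisson_tail_prob(int(round(lam)), float(lam)) >= 0.3
        counts = np.arange(1, 51)
        series = self.make_flat(counts)
        report = flag_outliers(series, np.arange(1, 51, dtype=float))
        assert not report.flags.any()

    def test_zero_counts_never_flagged(self):
        series = self.make_flat(np.zeros(20, dtype=np.int64))
        report = flag_outliers(series, np.full(20, 1e-6))
        assert not report.flags.any()
        assert (report.table["tail_prob"] == 1.0).all()

    def test_ranks_are_permutation(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(5.0, 200)
        counts[[10, 50, 90]] = [200, 400, 300]
        series = self.make_flat(counts)
        report = flag_outliers(series, np.full(200, 5.0))
        ranks = report.table.loc[report.table["flagged"], "rank"].to_numpy()
        assert sorted(ranks) == list(range(1, len(ranks) + 1))
        # Most extreme count has rank 1 even when tail probs underflow to 0.
        assert report.table.loc[50, "rank"] == 1

    def test_flag_monotone_in_threshold(self):
        rng = np.random.default_rng(15)
        counts = rng.poisson(3.0, 300)
        counts[7] = 40
        counts[200] = 15
        series = self.make_flat(counts)
        lam = np.full(300, 3.0)
        small = flag_outliers(series, lam, DetectionConfig(c=1e-6))
        large = flag_outliers(series, lam, DetectionConfig(c=1e-2))
        assert np.all(large.flags[small.flags])

    def test_invalid_inputs(self):
        series = self.make_flat([1, 2, 3])
        with pytest.raises(ValueError, match="length"):
            flag_outliers(series, np.ones(2))
        with pytest.raises(ValueError, match="positive"):
            flag_outliers(series, np.array([1.0, 0.0, 1.0]))
        with pytest.raises(ValueError, match="threshold"):
            DetectionConfig(c=1.5)


class TestDetect:
    def test_zero_refits_equals_single_pass(self):
        series = make_series(500, 10.0, seed=33)
        cfg = GamConfig(max_rank_s1=20)
        report = detect(series, cfg, DetectionConfig(max_refit_iterations=0))
        single = flag_outliers(
            series, BirthdateGAM(series, cfg).fit().lambda_hat, DetectionConfig()
        )
        assert np.array_equal(report.flags, single.flags)
        assert report.n_iterations == 0

    def test_refit_reduces_masking_bias(self):
        """A 1000x spike drags the local fit upward; refitting with the
        flagged date removed moves the intensity back toward truth."""
        n = 800
        lam_true = 8.0
        series = make_series(n, lam_true, seed=77, weekend=False)
        counts = series.counts.copy()
        spike = 400
        counts[spike] += int(1000 * lam_true)
        series = DailyCountSeries(series.dates, counts)
        cfg = GamConfig(max_rank_s1=30)

        res0 = BirthdateGAM(series, cfg).fit()
        report = detect(series, cfg, DetectionConfig(max_refit_iterations=1))
        assert report.flags[spike]
        assert report.table.loc[spike, "iteration_found"] == 0
        window = slice(spike - 10, spike + 11)
        err0 = np.abs(res0.lambda_hat[window] - lam_true).mean()
        err1 = np.abs(report.results.lambda_hat[window] - lam_true).mean()
        assert err1 < err0

    def test_refit_stable_on_clean_data(self):
        stable = 0
        n_seeds = 20
        for seed in range(n_seeds):
            series = make_series(600, 12.0, seed=900 + seed)
            cfg = GamConfig(max_rank_s1=16)
            report = detect(series, cfg, DetectionConfig(max_refit_iterations=1))
            base = flag_outliers(
                series, BirthdateGAM(series, cfg).fit().lambda_hat, DetectionConfig()
            )
            if not base.flags.any() or np.array_equal(report.flags, base.flags):
                stable += 1
        assert stable >= 0.95 * n_seeds
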