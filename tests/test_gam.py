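import dataclasses
import json
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from birthcheck.calendar_counts import CalendarConfig, DailyCountSeries, mark_special_days
from birthcheck.gam import (
    BirthdateGAM,
    GamConfig,
    build_design,
    fit_pirls,
    reproduce_intensity,
    select_smoothing,
)

from conftest import make_series


class TestBuildDesign:
    def test_no_special_days_degenerates_to_single_smooth(self):
        series = make_series(300, 10.0, seed=1, weekend=False)
        design = build_design(series, GamConfig())
        assert design.basis2 is None
        assert len(design.penalties) == 1

    def test_s2_rows_vanish_on_ordinary_days(self, flat_series):
        design = build_design(flat_series, GamConfig())
        X = design.X.toarray()
        s2_cols = X[:, 1 + design.basis1.rank :]
        weekdays = design.indicator == 0
        assert np.all(s2_cols[weekdays] == 0)
        assert np.any(s2_cols[~weekdays] != 0)

    def test_trend_smooth_centered(self, flat_series):
        """The centered s1 block has zero column sums after reparametrization."""
        design = build_design(flat_series, GamConfig())
        XZ = design.X @ design.Z
        s1_cols = XZ[:, 1 : design.basis1.rank]
        assert np.allclose(s1_cols.sum(axis=0), 0.0, atol=1e-8)

    def test_covariate_normalized(self, flat_series):
        design = build_design(flat_series, GamConfig())
        assert design.x[0] == 0.0 and design.x[-1] == 1.0

    def test_rank_reduction_warning(self):
        series = make_series(40, 10.0, seed=2)
        with pytest.warns(UserWarning, match="reducing"):
            build_design(series, GamConfig(max_rank_s1=100))

    def test_too_short_errors(self):
        series = make_series(8, 10.0, seed=3)
        with pytest.raises(ValueError, match="too short"):
            build_design(series, GamConfig())


class TestPIRLS:
    def test_constant_counts_heavy_smoothing_gives_constant_fit(self):
        n = 200
        series = DailyCountSeries(
            pd.date_range("1990-01-01", periods=n), np.full(n, 7, dtype=np.int64)
        )
        design = build_design(series, GamConfig(max_rank_s1=12))
        fit = fit_pirls(design, smoothing_params=(1e10,))
        assert np.allclose(fit.mu, 7.0, rtol=1e-6)

    def test_mean_preservation_score_equation(self, smooth_series):
        design = build_design(smooth_series, GamConfig())
        for sp in [(0.01, 0.01), (100.0, 1.0)]:
            fit = fit_pirls(design, smoothing_params=sp)
            total = design.counts.sum()
            assert abs(fit.mu.sum() - total) / total < 1e-6

    def test_positivity(self, smooth_series):
        design = build_design(smooth_series, GamConfig())
        fit = fit_pirls(design, smoothing_params=(1.0, 1.0))
        assert np.all(fit.mu > 0)

    def test_infinite_smoothing_reaches_null_space_glm(self, flat_series):
        """lambda -> inf leaves intercept + linear trend + (const, linear)
        weekend terms: the fit must match a plain Poisson GLM on exactly
        those columns."""
        design = build_design(flat_series, GamConfig())
        fit = fit_pirls(design, smoothing_params=(1e12, 1e12))
        assert abs(fit.edf_total - 4.0) < 1e-3
        X0 = np.column_stack(
            [
                np.ones(design.n),
                design.x,
                design.indicator,
                design.indicator * design.x,
            ]
        )
        glm = sm.GLM(design.counts, X0, family=sm.families.Poisson()).fit()
        assert abs(glm.deviance - fit.deviance) / glm.deviance < 1e-6

    def test_edf_monotone_in_smoothing(self, flat_series):
        design = build_design(flat_series, GamConfig())
        edfs = [
            fit_pirls(design, smoothing_params=(l1, 1.0)).edf_total
            for l1 in 10.0 ** np.arange(-3, 7)
        ]
        assert all(b <= a + 1e-6 for a, b in zip(edfs, edfs[1:]))

    def test_zero_weights_equal_row_deletion(self, flat_series):
        design = build_design(flat_series, GamConfig())
        n = design.n
        weights = np.ones(n)
        weights[100:160] = 0.0
        fit_w = fit_pirls(design, smoothing_params=(1.0, 1.0), weights=weights)
        keep = weights > 0
        sub = dataclasses.replace(
            design,
            X=design.X[keep],
            x=design.x[keep],
            indicator=design.indicator[keep],
            counts=design.counts[keep],
        )
        fit_d = fit_pirls(sub, smoothing_params=(1.0, 1.0))
        assert np.allclose(fit_w.beta_full, fit_d.beta_full, atol=1e-8)

    def test_negative_smoothing_rejected(self, flat_series):
        design = build_design(flat_series, GamConfig())
        with pytest.raises(ValueError):
            fit_pirls(design, smoothing_params=(-1.0, 1.0))

    def test_interpolation_limit_beats_smaller_rank(self):
        """Unpenalized saturated-rank fit attains deviance no worse than any
        smaller-rank fit on strictly positive counts."""
        n = 40
        rng = np.random.default_rng(9)
        counts = rng.poisson(20.0, n) + 1  # strictly positive
        series = DailyCountSeries(pd.date_range("2001-01-01", periods=n), counts)
        big = build_design(series, GamConfig(max_rank_s1=n - 11))
        small = build_design(series, GamConfig(max_rank_s1=6))
        dev_big = fit_pirls(big, smoothing_params=(0.0, 0.0)).deviance
        dev_small = fit_pirls(small, smoothing_params=(0.0, 0.0)).deviance
        assert dev_big <= dev_small + 1e-8


class TestSelectSmoothing:
    def test_singleton_grid_returns_that_point(self, flat_series):
        cfg = GamConfig(coarse_grid=1, n_refinements=0, log10_lambda_bounds=(0.5, 0.5))
        design = build_design(flat_series, cfg)
        sps, profile, fit = select_smoothing(design, cfg=cfg)
        assert sps == (10.0**0.5, 10.0**0.5)
        assert len(profile) == 1

    def test_pure_noise_selects_small_edf(self):
        edfs = []
        for seed in range(20):
            series = make_series(400, 20.0, seed=100 + seed, weekend=False)
            design = build_design(series, GamConfig())
            _, _, fit = select_smoothing(design, cfg=GamConfig())
            edfs.append(fit.edf_total)
        assert np.mean(edfs) <= 5.0

    def test_sinusoid_selects_larger_edf(self):
        n = 1000
        x = np.arange(n) / (n - 1)
        rng = np.random.default_rng(5)
        lam = np.exp(np.log(20.0) + 0.8 * np.sin(6 * np.pi * x))
        series = DailyCountSeries(
            pd.date_range("1970-01-01", periods=n), rng.poisson(lam)
        )
        design = build_design(series, GamConfig())
        _, _, fit = select_smoothing(design, cfg=GamConfig())
        assert fit.edf_total >= 8.0


@pytest.fixture(scope="module")
def fitted():
    n = 1500
    x = np.arange(n) / (n - 1)
    rng = np.random.default_rng(21)
    series = make_series(n, 1.0, seed=21)  # placeholder for indicator
    log_lam = np.log(18.0) + 0.6 * np.sin(2 * np.pi * x) - 0.5 * series.special
    counts = rng.poisson(np.exp(log_lam))
    series = DailyCountSeries(series.dates, counts, series.special)
    truth = np.exp(log_lam)
    return BirthdateGAM(series).fit(), truth


class TestFitAndPredict:

    def test_intensity_recovery(self, fitted):
        res, truth = fitted
        mask = res.design.indicator == 0
        rel = (res.lambda_hat[mask] - truth[mask]) / truth[mask]
        assert np.sqrt(np.mean(rel**2)) < 0.10

    def test_weekend_ratio_recovery(self, fitted):
        res, _ = fitted
        special = res.design.indicator == 1
        assert abs(res.s2_hat[special].mean() - (-0.5)) < 0.15

    def test_predict_matches_insample(self, fitted):
        res, _ = fitted
        pred = res.predict_intensity(res.series.dates)
        assert np.array_equal(pred, res.lambda_hat)

    def test_forced_indicator_ratio_is_exp_s2(self, fitted):
        res, _ = fitted
        day = res.series.dates[700:701]
        lam0 = res.predict_intensity(day, special=np.array([0.0]))
        lam1 = res.predict_intensity(day, special=np.array([1.0]))
        assert np.allclose(lam1 / lam0, np.exp(res.s2_hat[700]), rtol=1e-10)

    def test_midpoint_between_monotone_neighbors(self, fitted):
        res, _ = fitted
        lam = res.predict_intensity(
            res.series.dates, special=np.zeros(len(res.series))
        )
        i = next(
            i for i in range(200, 400) if lam[i] < lam[i + 1]
        )
        mid = res.series.dates[i] + pd.Timedelta(hours=12)
        val = res.predict_intensity(pd.DatetimeIndex([mid]), special=np.array([0.0]))[0]
        assert lam[i] <= val <= lam[i + 1]

    def test_extrapolation_requires_opt_in(self, fitted):
        res, _ = fitted
        beyond = pd.DatetimeIndex([res.series.dates[-1] + pd.Timedelta(days=30)])
        with pytest.raises(ValueError, match="extrapolation"):
            res.predict_intensity(beyond)
        val = res.predict_intensity(
            beyond, special=np.array([0.0]), allow_extrapolation=True
        )
        assert val[0] > 0

    def test_nested_model_deviance_unchanged_without_weekend_effect(self):
        """When the data carry no special-day effect, adding s2 changes the
        deviance by under 1% on average."""
        changes = []
        for seed in range(5):
            series = make_series(600, 15.0, seed=300 + seed)  # no true dip
            with_s2 = BirthdateGAM(series).fit()
            no_ind = DailyCountSeries(series.dates, series.counts)
            without_s2 = BirthdateGAM(no_ind).fit()
            changes.append(
                abs(with_s2.deviance - without_s2.deviance) / without_s2.deviance
            )
        assert np.mean(changes) < 0.01

    def test_json_roundtrip_reproduces_intensity_exactly(self, fitted):
        res, _ = fitted
        doc = res.to_json()
        lam = reproduce_intensity(json.loads(doc))
        assert np.array_equal(lam, res.lambda_hat)

    def test_summary_mentions_key_diagnostics(self, fitted):
        res, _ = fitted
        text = res.summary()
        assert "GCV" in text and "edf" in text and "converged" in text


class TestThinPlateAlternative:
    def test_fit_close_to_pspline(self):
        series = make_series(400, 12.0, seed=77)
        res_ps = BirthdateGAM(series, GamConfig(max_rank_s1=20)).fit()
        res_tp = BirthdateGAM(
            series, GamConfig(max_rank_s1=20, basis_kind="thin_plate_reduced")
        ).fit()
        rel = np.abs(res_tp.lambda_hat - res_ps.lambda_hat) / res_ps.lambda_hat
        assert np.mean(rel) < 0.05


def test_agreement_with_mgcv_reference():
    """Independent oracle: the same model fitted by mgcv (P-splines, GCV)
    must produce nearly the same intensity curve."""
    n = 400
    rng = np.random.default_rng(123)
    x = np.arange(n) / (n - 1)
    series = make_series(n, 1.0, seed=0)
    lam = np.exp(np.log(15.0) + 0.7 * np.sin(2 * np.pi * x) - 0.4 * series.special)
    counts = rng.poisson(lam)
    series = DailyCountSeries(series.dates, counts, series.special)
    res = BirthdateGAM(series, GamConfig(max_rank_s1=30, rank_s2=8)).fit()

    import tempfile, os

    with tempfile.TemporaryDirectory() as tmp:
        data = os.path.join(tmp, "d.csv")
        out = os.path.join(tmp, "o.csv")
        pd.DataFrame(
            {"y": counts, "x": x, "I": series.special.astype(int)}
        ).to_csv(data, index=False)
        script = os.path.join(tmp, "fit.R")
        with open(script, "w") as fh:
            fh.write(
                'library(mgcv)\n'
                f'd <- read.csv("{data}")\n'
                'fit <- gam(y ~ s(x, k=30, bs="ps") + s(x, k=8, bs="ps", by=I),\n'
                '           family=poisson, data=d, method="GCV.Cp")\n'
                f'write.csv(data.frame(lam=fitted(fit)), "{out}", row.names=FALSE)\n'
            )
        subprocess.run(
            ["Rscript", script], check=True, capture_output=True, timeout=300
        )
        mg = pd.read_csv(out)["lam"].to_numpy()
    rel = np.abs(res.lambda_hat - mg) / mg
    assert rel.mean() < 0.02
    assert np.corrcoef(res.lambda_hat, mg)[0, 1] > 0.999
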