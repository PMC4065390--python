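import numpy as np
import pandas as pd
import pytest

from birthcheck.calendar_counts import CalendarConfig, DailyCountSeries, mark_special_days


def make_series(
    n_days: int,
    lam,
    seed: int = 0,
    start: str = "1960-01-01",
    weekend: bool = True,
) -> DailyCountSeries:
    """Poisson series around a given intensity (scalar or array)."""
    rng = np.random.default_rng(seed)
    lam = np.broadcast_to(np.asarray(lam, dtype=float), (n_days,))
    counts = rng.poisson(lam)
    series = DailyCountSeries(pd.date_range(start, periods=n_days, freq="D"), counts)
    if weekend:
        series = mark_special_days(series, CalendarConfig())
    return series


@pytest.fixture
def flat_series() -> DailyCountSeries:
    """~2 years of counts around a constant intensity of 20, no weekend dip."""
    return make_series(730, 20.0, seed=42)


@pytest.fixture
def smooth_series() -> DailyCountSeries:
    """Smooth bumpy intensity between ~8 and ~45 with a -0.4 weekend ratio."""
    n = 1500
    x = np.arange(n) / (n - 1)
    rng = np.random.default_rng(7)
    log_lam = np.log(20.0) + 0.8 * np.sin(2 * np.pi * x) + 0.3 * x
    series = make_series(n, np.exp(log_lam), seed=7)
    lam = np.exp(log_lam - 0.4 * series.special)
    counts = rng.poisson(lam)
    return DailyCountSeries(series.dates, counts, series.special)
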