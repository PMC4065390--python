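"""Comparison detectors: seasonal ARIMA residuals and MAD smoothing.

Both operate on the same daily count series as the GAM detector but use a
single global threshold instead of a pointwise count distribution — which is
exactly the weakness the GAM approach addresses at the sparse ends of the
birthdate range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calendar_counts import DailyCountSeries

__all__ = [
    "SarimaSpec",
    "MadSpec",
    "sarima_detect",
    "mad_detect",
    "SarimaResult",
    "select_sarima_order",
]


@dataclass(frozen=True)
class SarimaSpec:
    """Seasonal ARIMA detector specification.

    Defaults mirror the high-order model selected for weekly-cyclic daily
    counts: ARIMA(0,1,5)x(0,0,2) with period 7, flagging one-step residuals
    above the one-sided 99.99th percentile of a fitted normal law.
    """

    order: tuple[int, int, int] = (0, 1, 5)
    seasonal_order: tuple[int, int, int] = (0, 0, 2)
    period: int = 7
    percentile: float = 0.9999
    robust_scale: bool = False
    maxiter: int = 60

    def __post_init__(self) -> None:
        if any(o < 0 for o in self.order + self.seasonal_order):
            raise ValueError("all ARIMA orders must be >= 0")
        if self.period < 1:
            raise ValueError("seasonal period must be >= 1")
        if not (0 < self.percentile < 1):
            raise ValueError("percentile must be in (0, 1)")

    @property
    def warm_up(self) -> int:
        """Number of initial one-step residuals discarded as start-up.

        Differencing spans plus the full moving-average memory: d + D*m +
        q + Q*m observations.
        """
        p, d, q = self.order
        ps, ds, qs = self.seasonal_order
        return d + ds * self.period + max(p + ps * self.period, q + qs * self.period)


@dataclass(frozen=True)
class MadSpec:
    """Sliding-window median / MAD detector specification.

    ``half_width`` is the window half-width in days (the window is the 2h
    neighbors of a point, excluding the point itself).  ``multiplier``
    defaults to the normal deviate whose one-sided tail is 1e-4, matching
    the 99.99th-percentile convention of the other detectors.  When the
    windowed MAD is zero, any value different from the windowed median is
    flagged (the degenerate policy that makes sparse range ends pathological
    for this detector).
    """

    half_width: int = 7
    multiplier: float = float(stats.norm.isf(1e-4))
    two_sided: bool = False

    def __post_init__(self) -> None:
        if self.half_width < 1:
            raise ValueError("half_width must be >= 1")


@dataclass
class SarimaResult:
    """Flags plus the residual diagnostics behind them."""

    flags: np.ndarray
    residuals: np.ndarray  # raw one-step residuals, NaN inside the warm-up
    scores: np.ndarray  # robustly standardized residuals (NaN in warm-up)
    threshold: float
    warm_up: int
    n_usable: int

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


def sarima_detect(series: DailyCountSeries, spec: SarimaSpec | None = None) -> SarimaResult:
    """Fit a seasonal ARIMA by maximum likelihood and threshold its residuals.

    A single global threshold — robust location plus ``z * `` robust scale of
    the post-warm-up residuals, one-sided at the configured percentile — is
    applied; there is no pointwise adaptation, so low-count dates at the
    range ends compete against the variance of the dense middle.
    """
    from statsmodels.tsa.statespace.sarimax import SARIMAX

    spec = spec or SarimaSpec()
    n = len(series)
    if n < 3 * spec.period:
        raise ValueError(
            f"series of length {n} is shorter than 3 seasonal periods "
            f"({3 * spec.period})"
        )
    if n <= spec.warm_up + 10:
        raise ValueError("series shorter than the model warm-up")

    y = series.counts.astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = SARIMAX(
            y,
            order=spec.order,
            seasonal_order=spec.seasonal_order + (spec.period,),
            trend=None,
            enforce_stationarity=True,
            enforce_invertibility=True,
            concentrate_scale=True,
            simple_differencing=True,
        )
        fitted = model.fit(disp=0, method="lbfgs", maxiter=spec.maxiter)
        resid_diff = np.asarray(fitted.resid, dtype=float)
    roots = []
    for name, poly in (
        ("AR", fitted.arroots),
        ("MA", fitted.maroots),
    ):
        bad = [r for r in np.atleast_1d(poly) if np.abs(r) <= 1.0 - 1e-10]
        if bad:
            roots.append(f"{name} roots {bad}")
    if roots:
        raise RuntimeError(
            "SARIMA fit is non-stationary/non-invertible: " + "; ".join(roots)
        )

    # With simple differencing the residual series starts d + D*period
    # observations in; align one-step residuals back to calendar positions.
    offset = spec.order[1] + spec.seasonal_order[1] * spec.period
    residuals = np.full(n, np.nan)
    residuals[offset : offset + len(resid_diff)] = resid_diff
    warm = spec.warm_up
    usable = residuals[warm:]
    med = float(np.median(usable))
    if spec.robust_scale:
        mad = float(np.median(np.abs(usable - med)))
        sd = 1.4826 * mad if mad > 0 else float(np.std(usable))
    else:
        # The comparator's normality assumption: a single global residual
        # standard deviation — inflated by any large spikes, which is
        # exactly what blinds a global threshold at the sparse range ends.
        sd = float(np.std(usable))
    z = float(stats.norm.ppf(spec.percentile))
    threshold = med + z * sd

    scores = np.full(n, np.nan)
    scores[warm:] = (usable - med) / sd if sd > 0 else 0.0
    flags = np.zeros(n, dtype=bool)
    flags[warm:] = usable > threshold
    return SarimaResult(
        flags=flags,
        residuals=residuals,
        scores=scores,
        threshold=threshold,
        warm_up=warm,
        n_usable=n - warm,
    )


def select_sarima_order(
    series: DailyCountSeries,
    candidates: list[tuple[tuple[int, int, int], tuple[int, int, int]]] | None = None,
    period: int = 7,
    maxiter: int = 50,
) -> SarimaSpec:
    """Optional information-criterion search over SARIMA orders.

    Fits each candidate ``(order, seasonal_order)`` by maximum likelihood
    and returns a :class:`SarimaSpec` with the AIC-minimizing pair.  The
    default candidate set is a small neighborhood of the weekly-cyclic
    moving-average family; candidates that fail to fit are skipped.
    """
    from statsmodels.tsa.statespace.sarimax import SARIMAX

    if candidates is None:
        candidates = [
            ((0, 1, q), (0, 0, Q)) for q in (1, 3, 5) for Q in (0, 1, 2)
        ]
    y = series.counts.astype(float)
    best: tuple[float, tuple, tuple] | None = None
    for order, seasonal in candidates:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fitted = SARIMAX(
                    y,
                    order=order,
                    seasonal_order=seasonal + (period,),
                    trend=None,
                    concentrate_scale=True,
                    simple_differencing=True,
                ).fit(disp=0, method="lbfgs", maxiter=maxiter)
            aic = float(fitted.aic)
        except Exception:
            continue
        if np.isfinite(aic) and (best is None or aic < best[0]):
            best = (aic, order, seasonal)
    if best is None:
        raise RuntimeError("no SARIMA candidate could be fitted")
    return SarimaSpec(order=best[1], seasonal_order=best[2], period=period)


def _window_neighbors(x: np.ndarray, i: int, h: int) -> np.ndarray:
    lo = max(0, i - h)
    hi = min(len(x), i + h + 1)
    return np.concatenate([x[lo:i], x[i + 1 : hi]])


def mad_detect(counts, spec: MadSpec | None = None) -> np.ndarray:
    """Sliding-window median/MAD spike detector.

    For each position, the signal estimate is the median of the windowed
    neighbors (the point itself excluded) and the spread is the median
    absolute deviation of those neighbors from that median; a point is
    flagged when it deviates from the signal by more than
    ``multiplier * spread``.  A zero spread degenerates to flagging any
    value unequal to the signal — for a window of mostly zeros every
    non-zero count is flagged, however small.
    """
    spec = spec or MadSpec()
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("counts must be a non-empty 1-D sequence")
    n = len(x)
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        nb = _window_neighbors(x, i, spec.half_width)
        if len(nb) == 0:
            continue
        signal = np.median(nb)
        spread = np.median(np.abs(nb - signal))
        dev = x[i] - signal
        if not spec.two_sided and dev <= 0:
            continue
        dev = abs(dev)
        if spread == 0:
            flags[i] = dev > 0
        else:
            flags[i] = dev > spec.multiplier * spread
    return flags
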