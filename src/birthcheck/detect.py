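"""Tail-probability outlier detection on fitted daily intensities.

A date ``d`` is suspect when its observed count ``N(d)`` is improbably large
under the fitted Poisson law: the detector computes the upper tail
probability ``P(K >= N(d) | lambda_hat(d))`` for every day and flags those
below a small threshold ``c`` (default 1e-4, the pointwise 99.99th
percentile).  Because the criterion is pointwise, sparse range ends are
handled gracefully: with a low fitted intensity the probability of seeing a
single individual is still appreciable, so isolated ones at the ends of the
age spectrum are not flagged.

Extreme spikes can drag the fitted intensity upward and mask lesser
anomalies; :func:`detect` optionally iterates fit -> flag -> refit with the
flagged dates given zero weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special as sps
from scipy import stats

from .calendar_counts import DailyCountSeries
from .gam import BirthdateGAM, GamConfig, GamConvergenceError, GAMResults

__all__ = [
    "DetectionConfig",
    "OutlierReport",
    "poisson_tail_prob",
    "poisson_quantile",
    "flag_outliers",
    "detect",
    "DetectionError",
]


class DetectionError(RuntimeError):
    """GAM fitting failed during detection; carries the last good report."""

    def __init__(self, message: str, partial_report: "OutlierReport | None"):
        super().__init__(message)
        self.partial_report = partial_report


@dataclass(frozen=True)
class DetectionConfig:
    """Detection threshold and refit policy.

    ``c`` is the tail-probability threshold (default 1e-4); ``bonferroni``
    divides it by the number of days; ``max_refit_iterations`` bounds the
    masking-mitigation loop (0 = single pass).
    """

    c: float = 1e-4
    max_refit_iterations: int = 1
    bonferroni: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.c < 1.0):
            raise ValueError("threshold c must be in (0, 1)")
        if self.max_refit_iterations < 0:
            raise ValueError("max_refit_iterations must be >= 0")

    def effective_c(self, n_days: int) -> float:
        return self.c / n_days if self.bonferroni else self.c


def poisson_tail_prob(n, lam):
    """Upper tail probability P(K >= n) for K ~ Poisson(lam).

    Computed through the regularized incomplete gamma function
    (``P(K >= n) = gammainc(n, lam)`` for n >= 1), which is numerically
    stable far into the tail; naive term summation is used nowhere.
    Vectorized over both arguments.  ``lam = 0`` returns 1 for ``n = 0``
    and 0 otherwise.
    """
    n_arr = np.asarray(n)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(n_arr < 0):
        raise ValueError("n must be non-negative")
    if np.any(lam_arr < 0):
        raise ValueError("lam must be non-negative")
    if not np.all(np.equal(np.mod(n_arr, 1), 0)):
        raise ValueError("n must be integer-valued")
    nf = n_arr.astype(float)
    with np.errstate(invalid="ignore"):
        out = np.where(nf == 0, 1.0, sps.gammainc(np.maximum(nf, 1.0), lam_arr))
    out = np.where((lam_arr == 0) & (nf > 0), 0.0, out)
    if np.isscalar(n) and np.isscalar(lam):
        return float(out)
    return out


def poisson_quantile(p, lam):
    """Smallest integer k with CDF(k; lam) >= p (the pointwise percentile)."""
    p_arr = np.asarray(p, dtype=float)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any((p_arr <= 0) | (p_arr >= 1)):
        raise ValueError("p must be in (0, 1)")
    if np.any(lam_arr < 0):
        raise ValueError("lam must be non-negative")
    out = stats.poisson.ppf(p_arr, lam_arr)
    out = np.where(lam_arr == 0, 0.0, out)
    if np.isscalar(p) and np.isscalar(lam):
        return int(out)
    return out.astype(np.int64)


@dataclass
class OutlierReport:
    """Per-date detection results.

    ``table`` has one row per day: date, count, expected, tail_prob, flagged,
    rank (1 = most extreme, NaN when not flagged) and iteration_found.
    """

    table: pd.DataFrame
    threshold: float
    n_iterations: int = 0
    method: str = "gam"
    results: GAMResults | None = field(default=None, repr=False)

    @property
    def flagged_dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.table.loc[self.table["flagged"], "date"])

    @property
    def flags(self) -> np.ndarray:
        return self.table["flagged"].to_numpy()

    @property
    def n_flagged(self) -> int:
        return int(self.table["flagged"].sum())

    def scores(self) -> np.ndarray:
        """Anomaly score per date: -log tail probability, underflow-safe."""
        n = self.table["count"].to_numpy(dtype=float)
        lam = self.table["expected"].to_numpy(dtype=float)
        return _neg_log_tail(n, lam)

    def to_csv(self, path: str) -> None:
        df = self.table.copy()
        df["date"] = pd.DatetimeIndex(df["date"]).strftime("%Y-%m-%d")
        df["expected"] = [f"{v:.6f}" for v in df["expected"]]
        df["tail_prob"] = [f"{v:.6e}" for v in df["tail_prob"]]
        df.to_csv(path, index=False)

    def summary_dict(self) -> dict:
        return {
            "method": self.method,
            "threshold": self.threshold,
            "n_days": int(len(self.table)),
            "n_flagged": self.n_flagged,
            "iterations": self.n_iterations,
        }


def _neg_log_tail(n: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """-log P(K >= n | lam), computed in log space to survive underflow.

    For tail probabilities below double precision the score falls back to a
    saddle-style bound using the leading term -log p(n; lam), which preserves
    the ranking among extreme spikes.
    """
    tail = poisson_tail_prob(n, lam)
    tail = np.asarray(tail, dtype=float)
    with np.errstate(divide="ignore"):
        score = -np.log(tail)
    under = ~np.isfinite(score)
    if np.any(under):
        nu, lu = n[under], np.maximum(lam[under], 1e-300)
        # -log of the leading Poisson pmf term at n (lower bound on the tail).
        score[under] = -(nu * np.log(lu) - lu - sps.gammaln(nu + 1.0))
    return score


def _rank_flags(
    tail: np.ndarray, counts: np.ndarray, lam: np.ndarray, flagged: np.ndarray
) -> np.ndarray:
    """Rank flagged dates: ascending tail probability; ties broken by the
    log-space count/intensity ratio (descending), then earlier date."""
    rank = np.full(len(tail), np.nan)
    idx = np.flatnonzero(flagged)
    if len(idx) == 0:
        return rank
    with np.errstate(divide="ignore"):
        log_ratio = np.log(np.maximum(counts[idx], 1e-300)) - np.log(
            np.maximum(lam[idx], 1e-300)
        )
    order = np.lexsort((idx, -log_ratio, tail[idx]))
    rank[idx[order]] = np.arange(1, len(idx) + 1)
    return rank


def flag_outliers(
    series: DailyCountSeries,
    lambda_hat: np.ndarray,
    cfg: DetectionConfig | None = None,
    method: str = "gam",
    results: GAMResults | None = None,
) -> OutlierReport:
    """Flag every date whose count has tail probability below the threshold.

    Zero counts are never flagged (their tail probability is 1 by
    definition).
    """
    cfg = cfg or DetectionConfig()
    lam = np.asarray(lambda_hat, dtype=float)
    if len(lam) != len(series):
        raise ValueError("lambda_hat length must match the series")
    if np.any(lam <= 0):
        raise ValueError("lambda_hat must be positive")
    counts = series.counts
    tail = np.asarray(poisson_tail_prob(counts, lam), dtype=float)
    c_eff = cfg.effective_c(len(series))
    flagged = tail < c_eff
    rank = _rank_flags(tail, counts.astype(float), lam, flagged)
    table = pd.DataFrame(
        {
            "date": series.dates,
            "count": counts,
            "expected": lam,
            "tail_prob": tail,
            "flagged": flagged,
            "rank": rank,
            "iteration_found": np.where(flagged, 0, -1),
        }
    )
    return OutlierReport(
        table=table, threshold=c_eff, n_iterations=0, method=method, results=results
    )


def detect(
    series: DailyCountSeries,
    gam_cfg: GamConfig | None = None,
    det_cfg: DetectionConfig | None = None,
) -> OutlierReport:
    """Full GAM-based detection with optional masking-mitigation refits.

    Iteration 0 fits on all dates and flags; each further iteration refits
    with previously flagged dates given weight zero, then re-flags over all
    dates.  Stops when the flag set stabilizes or ``max_refit_iterations``
    is reached; the final report carries the last iteration's intensity and
    records the iteration at which each flag first appeared.
    """
    det_cfg = det_cfg or DetectionConfig()
    model = BirthdateGAM(series, gam_cfg)
    weights = np.ones(len(series))
    try:
        res = model.fit()
    except GamConvergenceError as exc:
        raise DetectionError(f"initial GAM fit failed: {exc}", None) from exc
    report = flag_outliers(series, res.lambda_hat, det_cfg, results=res)
    first_seen = {
        d: 0 for d in np.flatnonzero(report.flags)
    }
    prev_flags = report.flags.copy()

    for it in range(1, det_cfg.max_refit_iterations + 1):
        if not prev_flags.any():
            break
        weights = np.where(prev_flags, 0.0, 1.0)
        try:
            res = model.fit(weights=weights)
        except GamConvergenceError as exc:
            raise DetectionError(
                f"GAM refit failed at iteration {it}: {exc}", report
            ) from exc
        report = flag_outliers(series, res.lambda_hat, det_cfg, results=res)
        for d in np.flatnonzero(report.flags):
            first_seen.setdefault(d, it)
        report.n_iterations = it
        if np.array_equal(report.flags, prev_flags):
            break
        prev_flags = report.flags.copy()

    iteration_found = np.full(len(series), -1)
    for d, it in first_seen.items():
        if report.flags[d]:
            iteration_found[d] = it
    report.table["iteration_found"] = iteration_found
    return report
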