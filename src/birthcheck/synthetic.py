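"""Labeled synthetic birthdate registers.

The generator emulates the statistical structure the intensity model
assumes of a real person-level register:

* a smooth multi-decade demographic trend (e.g. a depression-era dip and a
  post-war boom plateau), interpolated on the log scale through control
  points by a shape-preserving cubic;
* annual seasonality (log-scale sinusoid);
* a weekend birth ratio that drifts over the decades — historically slightly
  positive, turning negative as hospital births, elective Caesarean sections
  and induction concentrated births on weekdays;
* independent Poisson counts around the resulting intensity; and
* typed contamination injections (software zero dates, new-year rounding,
  decade rounding, year/age confusion, dispensing-date blocks, duplicated
  identities) with exact per-date ground-truth labels.

Everything is deterministic given (specs, seed).
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .calendar_counts import CalendarConfig, DailyCountSeries, mark_special_days

__all__ = [
    "TrueIntensitySpec",
    "Injection",
    "ContaminationSpec",
    "SyntheticDataset",
    "build_true_intensity",
    "sample_counts",
    "inject_contamination",
    "generate",
    "standard_register_intensity",
    "standard_contamination",
    "dense_register_intensity",
    "power_study_dataset",
]


def _year_fraction(dates: pd.DatetimeIndex) -> np.ndarray:
    return dates.year.to_numpy() + (dates.dayofyear.to_numpy() - 1) / 365.25


@dataclass(frozen=True)
class TrueIntensitySpec:
    """Ground-truth intensity: trend, seasonality and weekend ratio.

    ``trend_points`` and ``weekend_points`` are (decimal year, log value)
    control points interpolated by a monotone-preserving cubic (PCHIP), so
    the resulting log intensity is smooth and overshoot-free.  When
    ``target_total`` is set, the trend level is shifted so that the summed
    intensity over the range equals it exactly — the natural way to pin the
    expected register size.
    """

    start: str = "1890-01-01"
    end: str = "2012-12-31"
    base_log_level: float = 0.0
    trend_points: tuple[tuple[float, float], ...] = ()
    seasonal_amplitude: float = 0.05
    seasonal_phase: float = 0.0
    weekend_points: tuple[tuple[float, float], ...] = ((1900.0, 0.0),)
    holiday_log_ratio: float = 0.0
    target_total: float | None = None
    weekend_days: frozenset[int] = frozenset({6, 7})
    holidays: frozenset[_dt.date] = frozenset()

    def calendar_config(self) -> CalendarConfig:
        return CalendarConfig(
            weekend_days=self.weekend_days,
            holidays=self.holidays,
            treat_holidays_as_weekend=bool(self.holidays),
        )


@dataclass(frozen=True)
class Injection:
    """One contamination event.

    ``magnitude`` is an added count for the additive kinds, a multiplier for
    ``identity_duplication`` and the total added count for
    ``dispensing_block`` (spread over ``[date, end_date]``).  When
    ``relative`` is true the added count is ``magnitude *`` the local true
    intensity (rounded up), which spans easy/hard detection regimes
    uniformly across the age profile.
    """

    kind: str
    date: str
    magnitude: float
    end_date: str | None = None
    relative: bool = False
    block_days: int | None = None  # dispensing_block: distinct days hit

    KINDS = (
        "fill_date",
        "newyear_rounding",
        "decade_date",
        "year_age_confusion",
        "dispensing_block",
        "identity_duplication",
    )

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown contamination kind {self.kind!r}")
        if self.magnitude <= 0:
            raise ValueError("magnitude must be positive")


@dataclass(frozen=True)
class ContaminationSpec:
    """A list of injections plus an optional overall contamination fraction.

    When ``target_fraction`` is set, the additive magnitudes are rescaled so
    the total added count is that fraction of the clean total (e.g. 0.015
    for a register with 1.5% incorrect birthdates).
    """

    injections: tuple[Injection, ...] = ()
    target_fraction: float | None = None


@dataclass
class SyntheticDataset:
    """A generated register with full ground truth."""

    series: DailyCountSeries  # contaminated counts + special-day indicator
    clean_counts: np.ndarray
    lambda_true: np.ndarray
    truth: np.ndarray  # bool per date: was this date's count altered?
    kinds: list[str]  # ';'-joined kinds per date ('' when clean)
    seed: int
    intensity_spec: TrueIntensitySpec
    contamination_spec: ContaminationSpec

    @property
    def added_counts(self) -> np.ndarray:
        return self.series.counts - self.clean_counts

    def dump(self, counts_path: str, labels_path: str, sidecar_path: str) -> None:
        self.series.to_frame().to_csv(counts_path, index=False)
        lab = pd.DataFrame(
            {
                "date": self.series.dates.strftime("%Y-%m-%d"),
                "contaminated": self.truth.astype(int),
                "kind": self.kinds,
            }
        )
        lab[lab["contaminated"] == 1].to_csv(labels_path, index=False)
        side = {
            "seed": self.seed,
            "intensity_spec": _spec_to_jsonable(self.intensity_spec),
            "contamination_spec": {
                "target_fraction": self.contamination_spec.target_fraction,
                "injections": [asdict(i) for i in self.contamination_spec.injections],
            },
        }
        with open(sidecar_path, "w") as fh:
            json.dump(side, fh, indent=2)


def _spec_to_jsonable(spec: TrueIntensitySpec) -> dict:
    d = asdict(spec)
    d["weekend_days"] = sorted(spec.weekend_days)
    d["holidays"] = sorted(str(h) for h in spec.holidays)
    return d


def build_true_intensity(spec: TrueIntensitySpec) -> tuple[np.ndarray, DailyCountSeries]:
    """Evaluate the ground-truth intensity on the spec's date range.

    Returns ``(lambda_true, template_series)`` where the template series
    carries the dates and special-day indicator (counts all zero).
    Deterministic given the spec.
    """
    dates = pd.date_range(spec.start, spec.end, freq="D")
    template = DailyCountSeries(dates, np.zeros(len(dates), dtype=np.int64))
    template = mark_special_days(template, spec.calendar_config())
    yf = _year_fraction(dates)

    log_lam = np.full(len(dates), float(spec.base_log_level))
    if spec.trend_points:
        pts = sorted(spec.trend_points)
        xs = np.array([p[0] for p in pts])
        ys = np.array([p[1] for p in pts])
        interp = PchipInterpolator(xs, ys, extrapolate=True)
        log_lam = log_lam + interp(yf)
    if spec.seasonal_amplitude:
        doy = dates.dayofyear.to_numpy()
        log_lam = log_lam + spec.seasonal_amplitude * np.sin(
            2 * np.pi * (doy - 1) / 365.25 + spec.seasonal_phase
        )
    w = np.zeros(len(dates))
    if spec.weekend_points:
        pts = sorted(spec.weekend_points)
        if len(pts) == 1:
            w[:] = pts[0][1]
        else:
            xs = np.array([p[0] for p in pts])
            ys = np.array([p[1] for p in pts])
            w = PchipInterpolator(xs, ys, extrapolate=True)(yf)
    special = template.special.astype(float)
    log_lam = log_lam + special * w
    if spec.holiday_log_ratio and spec.holidays:
        hol = np.array([d.date() in spec.holidays for d in dates], dtype=float)
        log_lam = log_lam + hol * spec.holiday_log_ratio

    lam = np.exp(log_lam)
    if spec.target_total is not None:
        lam = lam * (spec.target_total / lam.sum())
    return lam, template


def sample_counts(lambda_true: np.ndarray, seed: int) -> np.ndarray:
    """Independent Poisson draws per date, reproducible given the seed."""
    rng = np.random.default_rng(seed)
    return rng.poisson(np.asarray(lambda_true, dtype=float)).astype(np.int64)


def _date_pos(dates: pd.DatetimeIndex, date: str) -> int:
    ts = pd.Timestamp(date)
    pos = int((ts - dates[0]).days)
    if pos < 0 or pos >= len(dates) or dates[pos] != ts:
        raise ValueError(f"injection date {date} outside the series range")
    return pos


def inject_contamination(
    clean_counts: np.ndarray,
    spec: ContaminationSpec,
    seed: int,
    dates: pd.DatetimeIndex,
    lambda_true: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Apply the configured injections to a clean count vector.

    Returns ``(contaminated, truth, kinds)``.  Overlapping injections sum
    their magnitudes and the label keeps every kind.  The dispensing-block
    kind spreads its total over the block dates via a seeded multinomial.
    """
    rng = np.random.default_rng(seed)
    n = len(clean_counts)
    contaminated = np.asarray(clean_counts, dtype=np.int64).copy()
    added = np.zeros(n, dtype=np.int64)
    mult = np.ones(n)
    kinds: list[set[str]] = [set() for _ in range(n)]

    def resolve(mag: float, relative: bool, pos: int) -> int:
        if relative:
            if lambda_true is None:
                raise ValueError("relative magnitudes require lambda_true")
            return max(1, int(np.ceil(mag * lambda_true[pos])))
        return max(1, int(round(mag)))

    scale = 1.0
    if spec.target_fraction is not None:
        base = 0
        for inj in spec.injections:
            if inj.kind == "identity_duplication":
                continue
            pos = _date_pos(dates, inj.date)
            base += resolve(inj.magnitude, inj.relative, pos)
        if base > 0:
            scale = spec.target_fraction * float(clean_counts.sum()) / base

    for inj in spec.injections:
        pos = _date_pos(dates, inj.date)
        if inj.kind == "identity_duplication":
            mult[pos] *= inj.magnitude
            kinds[pos].add(inj.kind)
        elif inj.kind == "dispensing_block":
            if inj.end_date is None:
                raise ValueError("dispensing_block requires end_date")
            end = _date_pos(dates, inj.end_date)
            if end < pos:
                raise ValueError("dispensing_block end_date before date")
            total = max(1, int(round(resolve(inj.magnitude, inj.relative, pos) * scale)))
            block = np.arange(pos, end + 1)
            if inj.block_days is not None and inj.block_days < len(block):
                # Contamination copies dispensing dates: a limited set of
                # operational days, each hit repeatedly.
                block = np.sort(
                    rng.choice(block, size=inj.block_days, replace=False)
                )
            alloc = rng.multinomial(total, np.full(len(block), 1.0 / len(block)))
            for b, a in zip(block, alloc):
                if a > 0:
                    added[b] += a
                    kinds[b].add(inj.kind)
        else:
            amount = max(1, int(round(resolve(inj.magnitude, inj.relative, pos) * scale)))
            added[pos] += amount
            kinds[pos].add(inj.kind)

    contaminated = contaminated + added
    dup = mult > 1.0
    contaminated[dup] = np.round(contaminated[dup] * mult[dup]).astype(np.int64)
    truth = np.array([len(k) > 0 for k in kinds])
    # A duplication on a zero-count date leaves the count unchanged; it is
    # still labeled only if the count actually changed.
    unchanged = contaminated == np.asarray(clean_counts, dtype=np.int64)
    truth = truth & ~unchanged
    kind_str = [
        ";".join(sorted(k)) if t else "" for k, t in zip(kinds, truth)
    ]
    return contaminated, truth, kind_str


def generate(
    intensity_spec: TrueIntensitySpec,
    contamination_spec: ContaminationSpec | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a fully labeled synthetic register from (specs, seed)."""
    contamination_spec = contamination_spec or ContaminationSpec()
    lam, template = build_true_intensity(intensity_spec)
    clean = sample_counts(lam, seed)
    contaminated, truth, kinds = inject_contamination(
        clean, contamination_spec, seed + 1, template.dates, lambda_true=lam
    )
    series = DailyCountSeries(template.dates, contaminated, template.special)
    return SyntheticDataset(
        series=series,
        clean_counts=clean,
        lambda_true=lam,
        truth=truth,
        kinds=kinds,
        seed=seed,
        intensity_spec=intensity_spec,
        contamination_spec=contamination_spec,
    )


def standard_register_intensity(target_total: float = 40_000.0) -> TrueIntensitySpec:
    """Scenario emulating a ~40,000-person register spanning 1890-2012.

    Trend control points encode sparse range ends, a dip in the early 1930s
    and an elevated plateau over 1946-1961; the weekend log ratio drifts from
    slightly positive before 1920 to about -0.6 by 2010.
    """
    return TrueIntensitySpec(
        start="1890-01-01",
        end="2012-12-31",
        trend_points=(
            (1890.0, -4.5),
            (1905.0, -1.2),
            (1920.0, 0.0),
            (1929.0, 0.1),
            (1933.5, -0.35),
            (1940.0, 0.1),
            (1946.0, 0.55),
            (1953.0, 0.65),
            (1961.0, 0.55),
            (1975.0, 0.1),
            (1990.0, -1.0),
            (2000.0, -2.5),
            (2008.0, -4.5),
            (2012.99, -6.0),
        ),
        seasonal_amplitude=0.05,
        weekend_points=((1890.0, 0.05), (1920.0, 0.0), (1960.0, -0.25), (2010.0, -0.6)),
        target_total=target_total,
    )


def standard_contamination() -> ContaminationSpec:
    """Typed injections echoing the documented contamination mechanisms.

    Software zero dates at the sparse left end, new-year/decade rounding and
    year-age confusion in the dense middle, a dispensing-date block at the
    recent end, and one duplicated identity.  Magnitudes are multiples of
    the local intensity (5x/20x/100x) except at the sparse ends, where
    absolute fill counts are used.
    """
    return ContaminationSpec(
        injections=(
            Injection("fill_date", "1899-12-30", 45),
            Injection("fill_date", "1900-01-01", 35),
            Injection("year_age_confusion", "1911-01-01", 30),
            Injection("decade_date", "1950-01-01", 20, relative=True),
            Injection("decade_date", "1960-01-01", 20, relative=True),
            Injection("newyear_rounding", "1963-02-14", 5, relative=True),
            Injection("fill_date", "1970-01-01", 100, relative=True),
            Injection("newyear_rounding", "1979-01-01", 5, relative=True),
            Injection("decade_date", "1980-01-01", 5, relative=True),
            Injection(
                "dispensing_block",
                "2006-01-01",
                300,
                end_date="2007-06-30",
                block_days=15,
            ),
            Injection("identity_duplication", "1955-06-15", 20.0),
        ),
    )


def dense_register_intensity(
    start: str = "1925-01-01",
    end: str = "1984-12-31",
    target_total: float = 160_000.0,
    weekend_log_ratio: float = -0.3,
) -> TrueIntensitySpec:
    """A denser register with sparse ends, for power/recovery studies.

    The middle decades sit at several expected births per day while both
    ends fall below 0.1/day, reproducing the sparse-tail regime where
    pointwise and global thresholds behave differently.
    """
    y0 = float(start[:4])
    y1 = float(end[:4]) + 0.99
    return TrueIntensitySpec(
        start=start,
        end=end,
        trend_points=(
            (y0, -9.0),
            (y0 + 8.0, -1.5),
            (y0 + 16.0, 0.3),
            ((y0 + y1) / 2, 0.7),
            (y1 - 16.0, 0.3),
            (y1 - 8.0, -1.5),
            (y1, -9.5),
        ),
        seasonal_amplitude=0.05,
        weekend_points=((y0, weekend_log_ratio),),
        target_total=target_total,
    )


def power_study_dataset(
    seed: int,
    target_total: float = 1_500_000.0,
    n_mid_spikes: int = 6,
    mid_multiple: float = 20.0,
    fill_count: int = 35,
) -> tuple[SyntheticDataset, np.ndarray, np.ndarray]:
    """Dense register with mid-range spikes and sparse-end zero-date fills.

    Mid spikes add ``mid_multiple`` times the local intensity on days where
    the expected count is at least 3; fills add ``fill_count`` individuals
    on four days at the range ends where the true intensity is below 0.1
    (two per end, deterministically chosen from the intensity profile).
    Returns the dataset plus the injected mid-spike and fill positions.
    """
    ispec = dense_register_intensity(target_total=target_total)
    lam, tmpl = build_true_intensity(ispec)
    dates = tmpl.dates
    sparse = (lam < 0.08) & (lam > 0.01)
    left = np.flatnonzero(sparse[: len(lam) // 2])
    right = np.flatnonzero(sparse)
    right = right[right >= len(lam) // 2]
    fill_pos = np.array([left[len(left) // 3], left[-1], right[0], right[len(right) // 2]])
    dense_pos = np.flatnonzero(lam >= 3.0)
    mid_pos = dense_pos[
        np.linspace(0, len(dense_pos) - 1, n_mid_spikes + 2).astype(int)[1:-1]
    ]
    injections = [
        Injection("fill_date", str(dates[p].date()), fill_count) for p in fill_pos
    ] + [
        Injection("decade_date", str(dates[p].date()), mid_multiple, relative=True)
        for p in mid_pos
    ]
    ds = generate(ispec, ContaminationSpec(injections=tuple(injections)), seed=seed)
    return ds, mid_pos, fill_pos
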