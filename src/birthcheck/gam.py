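"""Poisson generalized additive model for daily birthdate counts.

The model for the expected count (intensity) on day ``d`` is

    log lambda(d) = beta0 + s1(d) + I(d is special) * s2(d)

where ``s1`` is a smooth function of calendar time capturing the age profile
of the register (demographic trend plus seasonality) and ``s2`` is a smooth
function describing how the weekend/holiday birth ratio evolves over the
decades.  Both smooths are penalized regression splines; the smoothing
parameters are selected by generalized cross-validation (GCV) and the
penalized likelihood is maximized by iteratively reweighted least squares
(P-IRLS) under the canonical log link.

The public surface follows the model/results idiom: build a
:class:`BirthdateGAM` from a :class:`~birthcheck.calendar_counts.DailyCountSeries`,
call :meth:`~BirthdateGAM.fit`, and work with the returned
:class:`GAMResults` (fitted intensity, effective degrees of freedom, GCV
score, prediction, JSON round-trip).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

from .calendar_counts import DailyCountSeries
from .splines import SplineBasis, make_basis

__all__ = [
    "GamConfig",
    "GamDesign",
    "PIRLSFit",
    "GAMResults",
    "BirthdateGAM",
    "build_design",
    "fit_pirls",
    "select_smoothing",
    "fit_birthdate_gam",
]

_NS_PER_DAY = 86_400_000_000_000


class GamConvergenceError(RuntimeError):
    """P-IRLS diverged; carries the deviance trace for diagnosis."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class GamConfig:
    """Configuration of the birthdate GAM.

    Parameters
    ----------
    max_rank_s1
        Basis rank for the trend smooth s1.  ``None`` selects
        ``min(2 * years_covered, 200)``: two basis functions per year of data
        are enough to track annual seasonality, and the cap keeps the fit
        tractable on century-long registers.
    rank_s2
        Basis rank for the special-day smooth s2 (default 10; the weekend
        ratio drifts over decades, so a low rank suffices).
    basis_kind
        ``cubic_penalized`` (default) or ``thin_plate_reduced``.
    log10_lambda_bounds
        Search bounds for the two log10 smoothing parameters.
    coarse_grid, n_refinements
        GCV search: a coarse ``coarse_grid x coarse_grid`` grid followed by
        ``n_refinements`` shrinking 3x3 refinements around the minimum.
    tol, max_iter
        P-IRLS convergence: stop when the relative deviance change falls
        below ``tol`` or after ``max_iter`` iterations.
    """

    max_rank_s1: int | None = None
    rank_s2: int = 10
    basis_kind: str = "cubic_penalized"
    log10_lambda_bounds: tuple[float, float] = (-8.0, 8.0)
    coarse_grid: int = 5
    n_refinements: int = 2
    tol: float = 1e-8
    max_iter: int = 200

    def __post_init__(self) -> None:
        if self.max_rank_s1 is not None and self.max_rank_s1 < 3:
            raise ValueError("max_rank_s1 must be >= 3")
        if self.rank_s2 < 3:
            raise ValueError("rank_s2 must be >= 3")
        if self.tol <= 0:
            raise ValueError("tol must be positive")

    def resolve_rank_s1(self, n_days: int) -> int:
        if self.max_rank_s1 is not None:
            return self.max_rank_s1
        years = max(1, int(np.ceil(n_days / 365.25)))
        return int(min(max(2 * years, 10), 200))


@dataclass
class GamDesign:
    """Design and penalty matrices for one series.

    ``X`` holds the full (unconstrained) columns ``[1 | B1 | I * B2]``,
    sparse.  ``Z`` is the identifiability reparametrization: the trend smooth
    is centered (sum-to-zero over the fitting dates) by an orthonormal
    null-space transform, while the special-day smooth keeps its level — its
    columns vanish on ordinary days, so its constant is identified and
    centering it would make a constant weekend effect unrepresentable.
    """

    X: sp.csr_matrix
    Z: np.ndarray
    penalties: list[np.ndarray]  # reduced-coordinate penalty per smooth
    slices_full: list[slice]  # column ranges of s1, s2 in full coordinates
    basis1: SplineBasis
    basis2: SplineBasis | None
    x: np.ndarray  # normalized day index in [0, 1]
    indicator: np.ndarray
    counts: np.ndarray

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p_reduced(self) -> int:
        return self.Z.shape[1]

    def reduced_term_slices(self) -> list[slice]:
        """Coefficient ranges of (intercept, s1, s2) in reduced coordinates."""
        q1 = self.basis1.rank - 1  # one dof absorbed by centering
        out = [slice(0, 1), slice(1, 1 + q1)]
        if self.basis2 is not None:
            out.append(slice(1 + q1, 1 + q1 + self.basis2.rank))
        return out


def build_design(series: DailyCountSeries, cfg: GamConfig | None = None) -> GamDesign:
    """Build design and penalty matrices for the birthdate GAM.

    The covariate is the day index normalized to [0, 1].  When the series has
    no special days the s2 block is dropped and the model degenerates to a
    single-smooth fit.
    """
    cfg = cfg or GamConfig()
    n = len(series)
    if n < 10:
        raise ValueError(f"series too short to fit a GAM (n={n} < 10)")
    rank1 = cfg.resolve_rank_s1(n)
    rank2 = cfg.rank_s2
    if n < rank1 + rank2 + 1:
        new_rank1 = max(4, (n - rank2 - 1) // 2)
        warnings.warn(
            f"series length {n} cannot support rank {rank1}; reducing s1 rank to {new_rank1}",
            stacklevel=2,
        )
        rank1 = new_rank1
        if n < rank1 + rank2 + 1:
            rank2 = max(4, n - rank1 - 1)

    x = series.day_index / max(1, n - 1)
    indicator = series.special.astype(float)

    basis1 = make_basis(cfg.basis_kind, rank1)
    b1 = basis1.evaluate(x)

    has_s2 = bool(indicator.sum() > 0)
    basis2 = make_basis(cfg.basis_kind, rank2) if has_s2 else None
    blocks = [sp.csr_matrix(np.ones((n, 1))), b1]
    if basis2 is not None:
        b2 = basis2.evaluate(x).multiply(indicator[:, None]).tocsr()
        blocks.append(b2)
    X = sp.hstack(blocks, format="csr")

    # Centering transform for s1: orthonormal basis of the null space of the
    # column-sum constraint c' beta1 = 0.
    c1 = np.asarray(b1.sum(axis=0)).ravel()
    z1 = sla.null_space(c1[None, :])  # rank1 x (rank1 - 1)
    p_full = X.shape[1]
    p_red = 1 + (rank1 - 1) + (basis2.rank if basis2 is not None else 0)
    Z = np.zeros((p_full, p_red))
    Z[0, 0] = 1.0
    Z[1 : 1 + rank1, 1 : rank1] = z1
    slices_full = [slice(1, 1 + rank1)]
    if basis2 is not None:
        Z[1 + rank1 :, rank1 : rank1 + basis2.rank] = np.eye(basis2.rank)
        slices_full.append(slice(1 + rank1, 1 + rank1 + basis2.rank))

    # Penalties in reduced coordinates, embedded as p_red x p_red blocks.
    pen1 = np.zeros((p_red, p_red))
    pen1[1:rank1, 1:rank1] = z1.T @ basis1.penalty @ z1
    penalties = [pen1]
    if basis2 is not None:
        pen2 = np.zeros((p_red, p_red))
        pen2[rank1:, rank1:] = basis2.penalty
        penalties.append(pen2)

    return GamDesign(
        X=X,
        Z=Z,
        penalties=penalties,
        slices_full=slices_full,
        basis1=basis1,
        basis2=basis2,
        x=x,
        indicator=indicator,
        counts=series.counts.astype(float),
    )


@dataclass
class PIRLSFit:
    """Result of one penalized IRLS fit at fixed smoothing parameters."""

    beta_reduced: np.ndarray
    beta_full: np.ndarray
    mu: np.ndarray
    deviance: float
    edf_total: float
    edf_terms: list[float]
    converged: bool
    n_iter: int
    gcv: float


def _poisson_deviance(y: np.ndarray, mu: np.ndarray, w: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(np.where(y > 0, y / mu, 1.0)), 0.0)
    return float(2.0 * np.sum(w * (ylogy - (y - mu))))


def fit_pirls(
    design: GamDesign,
    counts: np.ndarray | None = None,
    smoothing_params: tuple[float, ...] = (1.0, 1.0),
    weights: np.ndarray | None = None,
    beta_start: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    score_tol: float = 1e-7,
) -> PIRLSFit:
    """Maximize the penalized Poisson log-likelihood by IRLS.

    ``smoothing_params`` are the per-smooth penalty multipliers (one per
    penalty in the design).  ``weights`` are 0/1 observation weights used by
    the refit-after-removal loop; zero-weight rows drop out of the likelihood
    exactly as if deleted.  Deviance decreases monotonically across accepted
    iterations (step halving); non-convergence is reported on the result,
    divergence raises :class:`GamConvergenceError` with the iteration trace.
    """
    y = design.counts if counts is None else np.asarray(counts, dtype=float)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    n = design.n
    wobs = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    sps = tuple(float(s) for s in smoothing_params[: len(design.penalties)])
    if any(s < 0 for s in sps):
        raise ValueError("smoothing parameters must be >= 0")
    S = sum(s * P for s, P in zip(sps, design.penalties))
    S = np.asarray(S)

    X, Z = design.X, design.Z
    # Dense radial bases (thin-plate) are faster through BLAS than through
    # sparse products; B-spline designs stay sparse.
    dense = X.nnz > 0.2 * X.shape[0] * X.shape[1]
    if dense:
        X = np.asarray(X.todense())
    if beta_start is not None:
        beta = beta_start.copy()
        eta = X @ (Z @ beta)
    else:
        beta = None
        eta = np.log(y + 0.5)
    eta = np.clip(eta, -30.0, 30.0)
    mu = np.exp(eta)

    def penalized(dev_val: float, b: np.ndarray | None) -> float:
        if b is None:
            return np.inf
        return dev_val + float(b @ (S @ b))

    # The objective P-IRLS decreases is the penalized deviance; the starting
    # working response is not a model fit, so monotonicity applies only
    # between accepted iterates.
    dev = np.inf if beta is None else _poisson_deviance(y, mu, wobs)
    pdev = penalized(dev, beta)
    trace: list[float] = [] if beta is None else [dev]
    converged = False
    A = None
    ridge_used = False

    total_weighted = float(np.sum(wobs * y))
    for it in range(1, max_iter + 1):
        w = wobs * mu
        z = eta + (y - mu) / mu
        if dense:
            Xw = X * w[:, None]
            A_full = X.T @ Xw
        else:
            Xw = X.multiply(w[:, None]).tocsr()
            A_full = (X.T @ Xw).toarray()
        b_full = X.T @ (w * z)
        A = Z.T @ A_full @ Z
        b = Z.T @ b_full
        try:
            cho = sla.cho_factor(A + S, lower=True)
            beta_new = sla.cho_solve(cho, b)
        except (sla.LinAlgError, np.linalg.LinAlgError):
            if not ridge_used:
                warnings.warn(
                    "singular working system; adding a small ridge", stacklevel=2
                )
                ridge_used = True
            ridge = 1e-8 * (np.trace(A) / A.shape[0] + 1.0)
            cho = sla.cho_factor(A + S + ridge * np.eye(A.shape[0]), lower=True)
            beta_new = sla.cho_solve(cho, b)

        # Step halving keeps the accepted penalized-deviance sequence
        # monotone.
        step = 1.0
        beta_prev = beta
        for _ in range(40):
            cand = beta_new if beta_prev is None else (
                beta_prev + step * (beta_new - beta_prev)
            )
            eta_c = np.clip(X @ (Z @ cand), -30.0, 30.0)
            mu_c = np.exp(eta_c)
            dev_c = _poisson_deviance(y, mu_c, wobs)
            pdev_c = penalized(dev_c, cand)
            ok = np.isfinite(pdev_c) and (
                beta_prev is None or pdev_c <= pdev + 1e-12 * (abs(pdev) + 1.0)
            )
            if ok:
                break
            if beta_prev is None:
                raise GamConvergenceError(
                    "P-IRLS diverged: non-finite deviance at the first step", trace
                )
            step /= 2.0
        else:
            raise GamConvergenceError(
                "P-IRLS diverged: penalized deviance would not decrease", trace
            )
        rel_change = (
            np.inf
            if not np.isfinite(pdev)
            else abs(pdev - pdev_c) / (abs(pdev_c) + 0.1)
        )
        beta, eta, mu = cand, eta_c, mu_c
        dev, pdev = dev_c, pdev_c
        trace.append(dev)
        # Converged when the penalized deviance has stabilized AND the
        # intercept score equation sum(w*(y - mu)) = 0 holds tightly (it is
        # exact at the optimum since the intercept is unpenalized).
        score_rel = abs(float(np.sum(wobs * (y - mu)))) / max(total_weighted, 1.0)
        if rel_change < tol and score_rel < score_tol:
            converged = True
            break

    # Effective degrees of freedom: trace of F = (A + S)^{-1} A at the final
    # weights (A recomputed so edf matches the converged fit).
    w = wobs * mu
    if dense:
        A = Z.T @ (X.T @ (X * w[:, None])) @ Z
    else:
        A = Z.T @ (X.T @ X.multiply(w[:, None]).tocsr()).toarray() @ Z
    try:
        F = sla.cho_solve(sla.cho_factor(A + S, lower=True), A)
    except (sla.LinAlgError, np.linalg.LinAlgError):
        ridge = 1e-8 * (np.trace(A) / A.shape[0] + 1.0)
        F = sla.cho_solve(
            sla.cho_factor(A + S + ridge * np.eye(A.shape[0]), lower=True), A
        )
    edf_total = float(np.trace(F))
    diag = np.diag(F)
    edf_terms = [float(diag[sl].sum()) for sl in design.reduced_term_slices()]

    n_eff = int(np.sum(wobs > 0))
    denom = max(n_eff - edf_total, 1e-8)
    gcv = n_eff * dev / denom**2

    return PIRLSFit(
        beta_reduced=beta,
        beta_full=Z @ beta,
        mu=mu,
        deviance=dev,
        edf_total=edf_total,
        edf_terms=edf_terms,
        converged=converged,
        n_iter=len(trace) - 1,
        gcv=gcv,
    )


def select_smoothing(
    design: GamDesign,
    counts: np.ndarray | None = None,
    cfg: GamConfig | None = None,
    weights: np.ndarray | None = None,
) -> tuple[tuple[float, ...], pd.DataFrame, PIRLSFit]:
    """Choose smoothing parameters minimizing GCV over a refined grid.

    GCV(rho) = n * D(rho) / (n - tr A(rho))^2 with D the Poisson deviance and
    tr A the effective degrees of freedom; each candidate is a full P-IRLS
    fit, warm-started from its neighbor.  Returns the selected parameters,
    the search profile and the winning fit.
    """
    cfg = cfg or GamConfig()
    n_pen = len(design.penalties)
    lo, hi = cfg.log10_lambda_bounds
    axes = [np.linspace(lo, hi, cfg.coarse_grid)] * n_pen

    profile: list[dict] = []
    best: tuple[float, PIRLSFit, tuple[float, ...]] | None = None
    beta_warm: np.ndarray | None = None

    def evaluate(point: tuple[float, ...]) -> None:
        nonlocal best, beta_warm
        sps = tuple(10.0**v for v in point)
        try:
            fit = fit_pirls(
                design,
                counts,
                sps,
                weights=weights,
                beta_start=beta_warm,
                tol=cfg.tol,
                max_iter=cfg.max_iter,
                score_tol=np.inf,  # grid search: penalized-deviance criterion
            )
        except GamConvergenceError:
            profile.append(
                {"log10_sp": point, "gcv": np.nan, "edf": np.nan, "converged": False}
            )
            return
        beta_warm = fit.beta_reduced
        profile.append(
            {
                "log10_sp": point,
                "gcv": fit.gcv,
                "edf": fit.edf_total,
                "converged": fit.converged,
            }
        )
        if fit.converged and (best is None or fit.gcv < best[0]):
            best = (fit.gcv, fit, point)

    import itertools

    for point in itertools.product(*axes):
        evaluate(point)
    if best is None:
        raise GamConvergenceError("no smoothing candidate converged", [])

    span = (hi - lo) / max(cfg.coarse_grid - 1, 1)
    for _ in range(cfg.n_refinements):
        center = best[2]
        axes = [
            np.clip(np.array([c - span / 2, c, c + span / 2]), lo, hi)
            for c in center
        ]
        seen = {tuple(p["log10_sp"]) for p in profile}
        for point in itertools.product(*axes):
            if tuple(point) not in seen:
                evaluate(tuple(point))
        span /= 2.0

    gcv_best, fit_best, point_best = best
    sps_best = tuple(10.0**v for v in point_best)
    # Polish the winner to a tight score-equation solution (warm-started,
    # usually one or two extra iterations).
    fit_best = fit_pirls(
        design,
        counts,
        sps_best,
        weights=weights,
        beta_start=fit_best.beta_reduced,
        tol=cfg.tol,
        max_iter=cfg.max_iter,
    )
    prof = pd.DataFrame(profile)
    return sps_best, prof, fit_best


class BirthdateGAM:
    """Poisson GAM for a daily birthdate count series.

    Parameters
    ----------
    series
        Dense daily counts with special-day indicator (see
        :mod:`birthcheck.calendar_counts`).
    config
        Model configuration; defaults follow the recommended practice of two
        basis functions per year of data capped at 200 degrees of freedom.

    Examples
    --------
    >>> model = BirthdateGAM(series)
    >>> res = model.fit()
    >>> res.lambda_hat  # fitted expected count per day
    """

    def __init__(self, series: DailyCountSeries, config: GamConfig | None = None):
        self.series = series
        self.config = config or GamConfig()
        self._design: GamDesign | None = None

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        date_col: str = "date",
        count_col: str = "count",
        special_col: str | None = "special",
        config: GamConfig | None = None,
    ) -> "BirthdateGAM":
        series = DailyCountSeries.from_frame(df, date_col=date_col, count_col=count_col)
        if special_col is not None and special_col in df.columns:
            special = np.asarray(df[special_col], dtype=np.int8)
            series = DailyCountSeries(series.dates, series.counts, special)
        return cls(series, config)

    @property
    def design(self) -> GamDesign:
        if self._design is None:
            self._design = build_design(self.series, self.config)
        return self._design

    def fit(self, weights: np.ndarray | None = None) -> "GAMResults":
        """Fit the model: GCV smoothing selection followed by P-IRLS.

        ``weights`` are optional 0/1 observation weights (used to exclude
        already-flagged dates when refitting).
        """
        design = self.design
        sps, profile, fit = select_smoothing(
            design, None, self.config, weights=weights
        )
        return GAMResults(
            model=self,
            design=design,
            pirls=fit,
            smoothing_params=sps,
            gcv_profile=profile,
            weights=None if weights is None else np.asarray(weights, float),
        )


class GAMResults:
    """Fitted birthdate GAM: intensity, smooth terms, diagnostics.

    Attributes
    ----------
    lambda_hat : np.ndarray
        Fitted intensity per fitting day (always positive).
    s1_hat, s2_hat : np.ndarray
        Values of the trend and special-day smooths on the fitting days
        (``s2_hat`` is the smooth itself; it contributes to the linear
        predictor only on special days).
    edf_terms, edf_total : effective degrees of freedom.
    gcv_score, deviance, converged : fit diagnostics.
    """

    def __init__(
        self,
        model: BirthdateGAM,
        design: GamDesign,
        pirls: PIRLSFit,
        smoothing_params: tuple[float, ...],
        gcv_profile: pd.DataFrame,
        weights: np.ndarray | None = None,
    ):
        self.model = model
        self.design = design
        self._pirls = pirls
        self.smoothing_params = smoothing_params
        self.gcv_profile = gcv_profile
        self.weights = weights

        beta = pirls.beta_full
        self.coefficients = beta
        self.intercept = float(beta[0])
        sl1 = design.slices_full[0]
        self.s1_hat = np.asarray(design.basis1.evaluate(design.x) @ beta[sl1])
        if design.basis2 is not None:
            sl2 = design.slices_full[1]
            # basis2 evaluated without the indicator: the smooth itself.
            self.s2_hat = np.asarray(design.basis2.evaluate(design.x) @ beta[sl2])
        else:
            self.s2_hat = np.zeros(design.n)
        self.eta = (
            self.intercept + self.s1_hat + design.indicator * self.s2_hat
        )
        # Recomputed blockwise so predict_intensity on the fitting dates is
        # bit-for-bit identical.
        self.lambda_hat = np.exp(np.clip(self.eta, -30.0, 30.0))
        self.edf_total = pirls.edf_total
        self.edf_terms = pirls.edf_terms
        self.gcv_score = pirls.gcv
        self.deviance = pirls.deviance
        self.converged = pirls.converged
        self.n_iter = pirls.n_iter

    @property
    def series(self) -> DailyCountSeries:
        return self.model.series

    def predict_intensity(
        self,
        dates: pd.DatetimeIndex | None = None,
        special: np.ndarray | None = None,
        allow_extrapolation: bool = False,
    ) -> np.ndarray:
        """Predict the intensity on given dates.

        On the fitting dates (the default) this reproduces ``lambda_hat``
        exactly.  Dates outside the fitted range raise unless
        ``allow_extrapolation`` is set.
        """
        if dates is None:
            return self.lambda_hat.copy()
        dates = pd.DatetimeIndex(dates)
        start = self.series.dates.asi8[0]
        offs = (dates.asi8 - start) / _NS_PER_DAY
        n = self.design.n
        xnew = offs / max(1, n - 1)
        if not allow_extrapolation and (xnew.min() < 0 or xnew.max() > 1):
            raise ValueError(
                "dates outside the fitted range; pass allow_extrapolation=True"
            )
        if special is None:
            inside = (offs >= 0) & (offs <= n - 1)
            special = np.zeros(len(dates))
            idx = offs[inside].astype(int)
            special[inside] = self.design.indicator[idx]
        special = np.asarray(special, dtype=float)
        beta = self.coefficients
        sl1 = self.design.slices_full[0]
        eta = self.intercept + np.asarray(
            self.design.basis1.evaluate(np.clip(xnew, 0, 1)) @ beta[sl1]
        )
        if self.design.basis2 is not None:
            sl2 = self.design.slices_full[1]
            eta = eta + special * np.asarray(
                self.design.basis2.evaluate(np.clip(xnew, 0, 1)) @ beta[sl2]
            )
        return np.exp(np.clip(eta, -30.0, 30.0))

    def summary(self) -> str:
        """Plain-text summary in the spirit of statsmodels results."""
        d = self.design
        lines = [
            "Poisson birthdate GAM",
            "=" * 46,
            f"n days:            {d.n}",
            f"basis:             {d.basis1.kind}",
            f"rank s1 / s2:      {d.basis1.rank} / "
            f"{d.basis2.rank if d.basis2 is not None else 0}",
            f"smoothing params:  "
            + ", ".join(f"{s:.4g}" for s in self.smoothing_params),
            f"edf (terms):       "
            + ", ".join(f"{e:.2f}" for e in self.edf_terms),
            f"edf total:         {self.edf_total:.2f}",
            f"GCV score:         {self.gcv_score:.6g}",
            f"deviance:          {self.deviance:.6g}",
            f"sum(lambda_hat):   {self.lambda_hat.sum():.4f}",
            f"sum(counts):       {d.counts.sum():.0f}",
            f"converged:         {self.converged} ({self.n_iter} iterations)",
        ]
        return "\n".join(lines)

    def to_json(self, path: str | None = None) -> str:
        """Serialize everything needed to reproduce lambda_hat exactly."""
        d = self.design
        doc = {
            "basis_kind": d.basis1.kind,
            "rank_s1": d.basis1.rank,
            "rank_s2": d.basis2.rank if d.basis2 is not None else 0,
            "knots_s1": d.basis1.knots.tolist(),
            "knots_s2": d.basis2.knots.tolist() if d.basis2 is not None else [],
            "coefficients": self.coefficients.tolist(),
            "smoothing_params": list(self.smoothing_params),
            "edf_terms": self.edf_terms,
            "edf_total": self.edf_total,
            "gcv_score": self.gcv_score,
            "deviance": self.deviance,
            "converged": self.converged,
            "start_date": str(self.series.dates[0].date()),
            "n_days": d.n,
            "indicator": d.indicator.astype(int).tolist(),
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def reproduce_intensity(doc: str | dict) -> np.ndarray:
    """Recompute lambda_hat from a :meth:`GAMResults.to_json` document."""
    if isinstance(doc, str):
        doc = json.loads(doc)
    n = int(doc["n_days"])
    x = np.arange(n) / max(1, n - 1)
    indicator = np.asarray(doc["indicator"], dtype=float)
    beta = np.asarray(doc["coefficients"], dtype=float)
    b1 = make_basis(doc["basis_kind"], int(doc["rank_s1"]))
    b1.knots = np.asarray(doc["knots_s1"])
    eta = beta[0] + np.asarray(b1.evaluate(x) @ beta[1 : 1 + b1.rank])
    if int(doc["rank_s2"]) > 0:
        b2 = make_basis(doc["basis_kind"], int(doc["rank_s2"]))
        b2.knots = np.asarray(doc["knots_s2"])
        eta = eta + indicator * np.asarray(
            b2.evaluate(x) @ beta[1 + b1.rank : 1 + b1.rank + b2.rank]
        )
    return np.exp(np.clip(eta, -30.0, 30.0))


def fit_birthdate_gam(
    series: DailyCountSeries,
    cfg: GamConfig | None = None,
    weights: np.ndarray | None = None,
) -> GAMResults:
    """Functional wrapper: build, select smoothing and fit in one call."""
    return BirthdateGAM(series, cfg).fit(weights=weights)
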