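"""Scoring of detector flags against ground truth.

The evaluation unit is the calendar date: a true positive is a date that was
truly contaminated and flagged.  Threshold-free comparison uses the ROC
curve and its area computed from per-date anomaly scores by the
rank (Mann-Whitney) statistic with tie correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ConfusionCounts", "EvalResult", "confusion", "metrics", "roc_auc"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class EvalResult:
    """Confusion counts and the derived detection metrics.

    Metrics with a zero denominator are ``None`` (undefined), never 0.
    ``auc`` is attached when scores were supplied.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    fnr: float | None
    auc: float | None = None

    def as_dict(self, ndigits: int = 4) -> dict:
        out: dict = {"TP": self.tp, "FP": self.fp, "FN": self.fn, "TN": self.tn}
        for name in ("sensitivity", "specificity", "ppv", "fnr", "auc"):
            v = getattr(self, name)
            out[name] = None if v is None else round(v, ndigits)
        return out

    def summary(self) -> str:
        d = self.as_dict()
        rows = [f"{k:>12}: {v if v is not None else 'undefined'}" for k, v in d.items()]
        return "\n".join(rows)


def confusion(flags, truth) -> ConfusionCounts:
    """Exhaustive date-level confusion counts; lengths must match."""
    f = np.asarray(flags, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if f.shape != t.shape:
        raise ValueError("flags and truth must have equal length")
    tp = int(np.sum(f & t))
    fp = int(np.sum(f & ~t))
    fn = int(np.sum(~f & t))
    tn = int(np.sum(~f & ~t))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics(
    conf: ConfusionCounts | None = None,
    tp: int | None = None,
    fp: int = 0,
    fn: int | None = None,
    tn: int = 0,
    auc: float | None = None,
) -> EvalResult:
    """Derive sensitivity/specificity/PPV/FNR from confusion counts.

    Accepts either a :class:`ConfusionCounts` or the raw counts; undefined
    ratios (empty class) are reported as ``None``.
    """
    if conf is None:
        conf = ConfusionCounts(tp=int(tp or 0), fp=int(fp), fn=int(fn or 0), tn=int(tn))

    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    return EvalResult(
        tp=conf.tp,
        fp=conf.fp,
        fn=conf.fn,
        tn=conf.tn,
        sensitivity=ratio(conf.tp, conf.tp + conf.fn),
        specificity=ratio(conf.tn, conf.tn + conf.fp),
        ppv=ratio(conf.tp, conf.tp + conf.fp),
        fnr=ratio(conf.fn, conf.tp + conf.fn),
        auc=auc,
    )


def roc_auc(scores, truth) -> tuple[float, pd.DataFrame]:
    """AUC via the rank statistic, plus the ROC curve points.

    Higher scores mean more anomalous.  Ties are handled by midranks
    (equivalently, each tied positive-negative pair contributes 1/2).
    Requires at least one positive and one negative; non-finite scores are
    ranked below every finite score.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=bool)
    if s.shape != t.shape:
        raise ValueError("scores and truth must have equal length")
    n_pos = int(t.sum())
    n_neg = int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes to be non-empty")
    s = np.where(np.isfinite(s), s, -np.inf)
    ranks = stats.rankdata(s)  # midranks for ties
    auc = (ranks[t].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    # Curve: sweep unique score thresholds from high to low.
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    t_sorted = t[order]
    tps = np.cumsum(t_sorted)
    fps = np.cumsum(~t_sorted)
    last_of_value = np.flatnonzero(s_sorted[:-1] != s_sorted[1:])
    idx = np.concatenate([last_of_value, [len(s_sorted) - 1]])
    curve = pd.DataFrame(
        {
            "threshold": s_sorted[idx],
            "tpr": tps[idx] / n_pos,
            "fpr": fps[idx] / n_neg,
        }
    )
    curve = pd.concat(
        [pd.DataFrame({"threshold": [np.inf], "tpr": [0.0], "fpr": [0.0]}), curve],
        ignore_index=True,
    )
    return float(auc), curve
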