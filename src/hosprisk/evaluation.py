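"""Model scoring: AUC with confidence interval, information criteria,
optimal-cutoff threshold metrics, and performance by length of stay.

The AUC is the Mann–Whitney pairwise concordance (ties count ½); its
confidence interval uses DeLong's asymptotic variance by default, with a
stratified bootstrap as an option.  The operating point is the threshold
maximizing sensitivity + specificity (Youden's rule), with sensitivity,
specificity, PPV, NPV and accuracy reported there as percentages.
AIC = 2k − 2L and BIC = k·ln(n) − 2L are computed from the training fit
(they are training-likelihood quantities); AUC and threshold metrics
come from the held-out data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_auc_score, roc_curve

from .models import FittedModel, predict_risk, prepare_features

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AucResult:
    auc: float
    ci_low: float
    ci_high: float
    se: float
    method: str

    def as_tuple(self) -> tuple[float, float, float]:
        return self.auc, self.ci_low, self.ci_high


@dataclass(frozen=True)
class CutoffMetrics:
    """Threshold metrics at the Youden-optimal cutoff (percent scale).

    ``cutoff`` is on the predicted-probability scale; ``cutoff_odds`` is
    the same point expressed as the odds p/(1−p), the "ratio of deaths
    to survival" phrasing used alongside published cutoffs.  PPV/NPV are
    NaN when no record is predicted in the corresponding class.
    """

    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float

    @property
    def cutoff_odds(self) -> float:
        return self.cutoff / (1.0 - self.cutoff) if self.cutoff < 1.0 else math.inf


@dataclass
class EvaluationReport:
    auc: AucResult
    aic: float
    bic: float
    cutoff: CutoffMetrics
    n_test: int
    by_los: pd.DataFrame | None = None

    def as_row(self) -> dict:
        return {
            "auc": self.auc.auc,
            "auc_ci_low": self.auc.ci_low,
            "auc_ci_high": self.auc.ci_high,
            "aic": self.aic,
            "bic": self.bic,
            "cutoff": self.cutoff.cutoff,
            "cutoff_odds": self.cutoff.cutoff_odds,
            "sensitivity": self.cutoff.sensitivity,
            "specificity": self.cutoff.specificity,
            "ppv": self.cutoff.ppv,
            "npv": self.cutoff.npv,
            "accuracy": self.cutoff.accuracy,
            "n_test": self.n_test,
        }


def _check_two_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == 0
    if not pos.any() or not neg.any():
        raise ValueError("both outcome classes must be present")
    return pos, neg


def roc_auc(
    scores,
    labels,
    method: str = "delong",
    alpha: float = 0.05,
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> AucResult:
    """AUC (pairwise concordance with ties at ½) and its CI.

    ``method='delong'`` (default) uses the asymptotic placement-value
    variance; ``method='bootstrap'`` a stratified bootstrap.
    """
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_classes(labels)
    x, ycls = scores[pos], scores[neg]
    m, n = len(x), len(ycls)
    auc = float(roc_auc_score(np.asarray(labels), scores))
    z = norm.ppf(1 - alpha / 2)
    if method == "delong":
        r_all = rankdata(np.concatenate([x, ycls]))
        rx = rankdata(x)
        ry = rankdata(ycls)
        # placement values: per-positive and per-negative concordance
        v10 = (r_all[:m] - rx) / n
        v01 = 1.0 - (r_all[m:] - ry) / m
        s10 = v10.var(ddof=1) if m > 1 else 0.0
        s01 = v01.var(ddof=1) if n > 1 else 0.0
        se = math.sqrt(s10 / m + s01 / n)
    elif method == "bootstrap":
        gen = np.random.default_rng(rng)
        stats = np.empty(n_boot)
        for i in range(n_boot):
            xb = gen.choice(x, size=m, replace=True)
            yb = gen.choice(ycls, size=n, replace=True)
            stats[i] = _pairwise_auc(xb, yb)
        se = float(stats.std(ddof=1))
    else:
        raise ValueError(f"unknown CI method {method!r}")
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return AucResult(auc, lo, hi, se, method)


def _pairwise_auc(x: np.ndarray, y: np.ndarray) -> float:
    """Mann–Whitney concordance via mid-ranks (O(N log N))."""
    m, n = len(x), len(y)
    r = rankdata(np.concatenate([x, y]))
    return (r[:m].sum() - m * (m + 1) / 2) / (m * n)


def information_criteria(model: FittedModel | tuple) -> tuple[float, float]:
    """(AIC, BIC) = (2k − 2L, k·ln(n) − 2L) from a fitted model or a raw
    (log-likelihood, k, n) triple."""
    if isinstance(model, tuple):
        llf, k, n = model
    else:
        llf, k, n = model.llf, model.k, model.n
    aic = 2.0 * k - 2.0 * llf
    bic = k * math.log(n) - 2.0 * llf
    return aic, bic


def optimal_cutoff(scores, labels) -> CutoffMetrics:
    """Threshold maximizing sensitivity + specificity.

    Candidate thresholds are the distinct scores; a record is predicted
    positive when score ≥ cutoff.  Ties in the objective break toward
    the higher threshold (higher specificity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    # roc_curve thresholds scan score >= t, descending; drop the sentinel
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    keep = np.isfinite(thresholds)
    fpr, tpr, thresholds = fpr[keep], tpr[keep], thresholds[keep]
    j = tpr + (1 - fpr)
    # thresholds are descending: first argmax is the highest cutoff,
    # i.e. the most specific among ties
    best = int(np.argmax(j))
    cut = float(thresholds[best])
    return _metrics_at(scores, labels, cut)


def _metrics_at(scores: np.ndarray, labels: np.ndarray, cutoff: float) -> CutoffMetrics:
    pred = scores >= cutoff
    pos = labels == 1
    tp = float(np.sum(pred & pos))
    fp = float(np.sum(pred & ~pos))
    fn = float(np.sum(~pred & pos))
    tn = float(np.sum(~pred & ~pos))
    sens = 100.0 * tp / (tp + fn) if tp + fn else math.nan
    spec = 100.0 * tn / (tn + fp) if tn + fp else math.nan
    ppv = 100.0 * tp / (tp + fp) if tp + fp else math.nan
    npv = 100.0 * tn / (tn + fn) if tn + fn else math.nan
    acc = 100.0 * (tp + tn) / len(labels)
    return CutoffMetrics(cutoff, sens, spec, ppv, npv, acc)


def evaluate(
    model: FittedModel,
    test_records: pd.DataFrame,
    ci_method: str = "delong",
    by_los_max_day: int | None = None,
) -> EvaluationReport:
    """Score a trained model on held-out records.

    AUC (with CI) and the optimal-cutoff metrics are computed on the
    test records; AIC/BIC carry over from the training fit stored in
    the model.
    """
    data = prepare_features(test_records)
    if model.spec.subgroup is not None:
        col, val = model.spec.subgroup
        data = data[data[col] == val]
        if data.empty:
            raise ValueError(f"no test records in subgroup {col} == {val!r}")
    scores = predict_risk(model, data)
    y = data["y"].to_numpy()
    auc = roc_auc(scores, y, method=ci_method)
    aic, bic = information_criteria(model)
    cut = optimal_cutoff(scores, y)
    by_los = (
        evaluate_by_los(model, data, max_day=by_los_max_day)
        if by_los_max_day
        else None
    )
    return EvaluationReport(auc, aic, bic, cut, n_test=len(data), by_los=by_los)


def evaluate_by_los(
    model: FittedModel, test_records: pd.DataFrame, max_day: int = 28
) -> pd.DataFrame:
    """AUC/sensitivity/specificity by integer day of stay.

    Records are bucketed by ceil(LOS) with same-day stays in bucket 1
    and stays of ``max_day`` days or longer pooled into a final bucket.
    Buckets containing a single outcome class report NaN metrics.
    """
    if max_day < 1:
        raise ValueError("max_day must be >= 1")
    data = prepare_features(test_records)
    scores = predict_risk(model, data)
    y = data["y"].to_numpy()
    los = data["los_days"].to_numpy()
    day = np.maximum(1, np.ceil(los)).astype(int)
    day = np.minimum(day, max_day)
    rows = []
    for d in range(1, max_day + 1):
        mask = day == d
        n_d = int(mask.sum())
        deaths = int(y[mask].sum())
        row = {
            "los_day": d,
            "pooled_tail": d == max_day,
            "n": n_d,
            "deaths": deaths,
            "auc": math.nan,
            "sensitivity": math.nan,
            "specificity": math.nan,
        }
        if n_d and 0 < deaths < n_d:
            auc = roc_auc(scores[mask], y[mask])
            cut = optimal_cutoff(scores[mask], y[mask])
            row.update(
                auc=auc.auc, sensitivity=cut.sensitivity, specificity=cut.specificity
            )
        elif n_d:
            logger.debug("LOS bucket %d has a single outcome class; metrics absent", d)
        rows.append(row)
    return pd.DataFrame(rows)
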