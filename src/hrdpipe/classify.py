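"""HRD-tumor classification and ROC analysis.

Tumors are classified as HRD either by a top-quantile rule on the cohort's
own score distribution (default top 10%, tie groups kept together) or by a
fixed score cutoff (score >= cutoff, inclusive).  ROC analysis evaluates a
score against a binary label with the higher-score-is-positive convention,
reports the trapezoidal AUC, and selects the cutoff maximizing
sensitivity + specificity (ties broken toward the lowest threshold, which
favours sensitivity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)


@dataclass
class HrdClassification:
    """Per-sample HRD class under a stated rule."""

    table: pd.DataFrame  # columns: sample, hrd_score, cohort_quantile, is_hrd_top
    rule: str
    threshold: float | None

    @property
    def n_hrd(self) -> int:
        return int(self.table["is_hrd_top"].sum())


def classify_by_quantile(scores: pd.Series, q: float = 0.10) -> HrdClassification:
    """Top-quantile classification with whole tie groups kept together.

    The realized threshold is the smallest score such that the fraction of
    samples at or above it does not exceed ``q``; all samples tied at a
    score are classified together (equal scores are never split across
    classes).
    """
    s = pd.Series(scores).astype(float)
    if s.size == 0:
        raise DataError("no scores to classify")
    if s.isna().any():
        raise DataError("scores must be non-missing")
    n = s.size
    threshold = None
    for value in np.sort(s.unique()):
        frac = (s >= value).sum() / n
        if frac <= q:
            threshold = float(value)
            break
    if threshold is None:
        is_top = pd.Series(False, index=s.index)
        logger.warning("no score satisfies the top-%.0f%% rule; empty HRD class", q * 100)
    else:
        is_top = s >= threshold
    quantile = s.rank(pct=True, method="max")
    table = pd.DataFrame(
        {
            "sample": s.index,
            "hrd_score": s.to_numpy(),
            "cohort_quantile": quantile.to_numpy(),
            "is_hrd_top": is_top.to_numpy(),
        }
    )
    return HrdClassification(table=table, rule=f"top_quantile {q}", threshold=threshold)


def classify_by_cutoff(scores: pd.Series, cutoff: float = 57) -> HrdClassification:
    """Fixed-cutoff classification: HRD iff score >= cutoff (inclusive)."""
    s = pd.Series(scores).astype(float)
    quantile = s.rank(pct=True, method="max") if s.size else pd.Series(dtype=float)
    table = pd.DataFrame(
        {
            "sample": s.index,
            "hrd_score": s.to_numpy(),
            "cohort_quantile": quantile.to_numpy(),
            "is_hrd_top": (s >= cutoff).to_numpy() if s.size else np.array([], dtype=bool),
        }
    )
    return HrdClassification(table=table, rule=f"fixed_cutoff {cutoff}", threshold=float(cutoff))


@dataclass
class RocResult:
    """ROC curve, AUC, and the best sensitivity+specificity cutoff."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    best_cutoff: float
    best_sens: float
    best_spec: float

    @property
    def youden_sum(self) -> float:
        return self.best_sens + self.best_spec


def roc_curve(scores, labels) -> RocResult:
    """ROC of a score against binary labels (score >= t predicts positive).

    Thresholds are the unique scores plus sentinels beyond both ends; AUC
    is computed by the trapezoidal rule over (FPR, TPR).  The best cutoff
    maximizes sensitivity + specificity; exact ties go to the lowest
    threshold (logged).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape or s.ndim != 1:
        raise DataError("scores and labels must be aligned 1-D vectors")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("ROC needs both classes present")
    uniq = np.unique(s)
    thresholds = np.concatenate([[-np.inf], uniq, [np.inf]])
    sens = np.array([(s[y] >= t).mean() for t in thresholds])
    spec = np.array([(s[~y] < t).mean() for t in thresholds])
    fpr = 1.0 - spec
    # walk the curve from the strictest threshold (0,0) to the laxest
    # (1,1); along this path FPR is non-decreasing and the trapezoid rule
    # integrates the ROC correctly even with tied FPR values
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))
    sums = sens + spec
    best_sum = sums.max()
    candidates = thresholds[np.isclose(sums, best_sum)]
    best = float(candidates.min())
    if len(candidates) > 1:
        logger.info(
            "best-cutoff tie among %d thresholds; taking lowest (%g)",
            len(candidates), best,
        )
    i = int(np.flatnonzero(thresholds == best)[0])
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        best_cutoff=best,
        best_sens=float(sens[i]),
        best_spec=float(spec[i]),
    )


def compare_predictors(
    predictor_map: dict[str, pd.Series], labels: pd.Series
) -> dict[str, RocResult]:
    """ROC per predictor on the intersection of non-missing samples."""
    labels = pd.Series(labels)
    common = labels.dropna().index
    for s in predictor_map.values():
        common = common.intersection(pd.Series(s).dropna().index)
    if len(common) == 0:
        raise DataError("no common non-missing samples across predictors")
    out = {}
    for name, s in predictor_map.items():
        s = pd.Series(s).loc[common]
        out[name] = roc_curve(s.to_numpy(), labels.loc[common].to_numpy())
    return out
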