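"""Group-comparison statistics for cohort contrasts.

Wilcoxon rank-sum tests (exact by enumeration for small groups, tie-
corrected normal approximation otherwise), one-vs-rest comparisons for
three or more groups, Benjamini-Hochberg FDR control, differential
expression on FPKM with fold-change and FDR thresholds, a six-gene IFN-γ
signature score, Tukey-fence outlier removal, and the linear fit of
mutation burden on signature activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .errors import DataError

logger = logging.getLogger(__name__)

IFNG_GENES = ("IDO1", "CXCL10", "CXCL9", "HLA-DRA", "STAT1", "IFNG")


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumeration of all group splits.

    Uses midranks, so ties are handled; the p-value is the fraction of
    splits whose rank-sum deviates from its expectation by at least the
    observed amount.
    """
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    expected = n1 * (len(pooled) + 1) / 2.0
    dev = abs(obs - expected)
    hits = 0
    total = comb(len(pooled), n1)
    for idx in combinations(range(len(pooled)), n1):
        if abs(ranks[list(idx)].sum() - expected) >= dev - 1e-9:
            hits += 1
    return hits / total


def ranksum_test(
    x, y, exact_threshold: int = 8
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Exact (full enumeration, tie-aware) when both groups have at most
    ``exact_threshold`` observations; tie-corrected normal approximation
    otherwise.  Returns (rank-sum statistic of the first group, p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("rank-sum test needs two non-empty groups")
    pooled = np.concatenate([x, y])
    stat = float(scipy.stats.rankdata(pooled)[: x.size].sum())
    if max(x.size, y.size) <= exact_threshold:
        return stat, _exact_ranksum_p(x, y)
    _, p = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return stat, float(p)


def one_vs_rest(groups, values, exact_threshold: int = 8) -> dict[str, float]:
    """Per-label rank-sum p-values, each label against all other samples.

    Requires at least three distinct labels (use :func:`ranksum_test`
    directly for two); an empty label is skipped with a warning.
    """
    groups = np.asarray(groups, dtype=object)
    values = np.asarray(values, dtype=float)
    labels = pd.unique(groups)
    if len(labels) < 3:
        raise DataError(
            "one-vs-rest needs at least 3 groups; use ranksum_test for two"
        )
    out: dict[str, float] = {}
    for label in labels:
        mask = groups == label
        if mask.sum() == 0 or (~mask).sum() == 0:
            logger.warning("label %r has no usable split; skipped", label)
            continue
        _, p = ranksum_test(values[mask], values[~mask], exact_threshold=exact_threshold)
        out[str(label)] = p
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------


def select_degs(
    expr: pd.DataFrame,
    group1: list[str],
    group2: list[str],
    fc_cut: float = 1.5,
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """Differentially expressed genes between two sample groups.

    Per gene: fold change = mean FPKM(group2) / mean FPKM(group1),
    rank-sum p-value, BH adjustment over all tested genes; selected iff
    |log2 FC| > ``fc_cut`` and adjusted p < ``q_cut`` (both strict).
    Genes with zero mean in either group have no finite log fold change
    and are excluded from testing with a logged count.
    """
    overlap = set(group1) & set(group2)
    if overlap:
        raise DataError(f"groups overlap: {sorted(overlap)[:5]}")
    if not group1 or not group2:
        raise DataError("both groups must be non-empty")
    X1 = expr.loc[:, list(group1)].to_numpy(dtype=float)
    X2 = expr.loc[:, list(group2)].to_numpy(dtype=float)
    mean1 = X1.mean(axis=1)
    mean2 = X2.mean(axis=1)
    testable = (mean1 > 0) & (mean2 > 0)
    n_dropped = int((~testable).sum())
    if n_dropped:
        logger.info("excluded %d gene(s) with zero group mean from DEG testing", n_dropped)
    idx = np.flatnonzero(testable)
    fc = mean2[idx] / mean1[idx]
    log2fc = np.log2(fc)
    if idx.size:
        _, p = scipy.stats.mannwhitneyu(
            X1[idx], X2[idx], alternative="two-sided", method="asymptotic", axis=1
        )
        adj = bh_adjust(p)
    else:
        p = np.array([])
        adj = np.array([])
    out = pd.DataFrame(
        {
            "gene": expr.index[idx],
            "mean_fpkm_group1": mean1[idx],
            "mean_fpkm_group2": mean2[idx],
            "fc": fc,
            "log2fc": log2fc,
            "p_value": p,
            "adj_p": adj,
        }
    )
    out["selected"] = (out["log2fc"].abs() > fc_cut) & (out["adj_p"] < q_cut)
    return out.set_index("gene")


def ifng_signature(
    expr: pd.DataFrame,
    genes: tuple[str, ...] = IFNG_GENES,
    log_scale: bool = True,
) -> pd.Series:
    """Per-sample IFN-γ signature: mean expression of six immune genes.

    Uses log2(FPKM + 1) by default (raw FPKM with ``log_scale=False``).
    Missing genes are dropped with a warning; if none of the genes is
    present an error is raised.
    """
    present = [g for g in genes if g in expr.index]
    missing = [g for g in genes if g not in expr.index]
    if not present:
        raise DataError(f"none of the signature genes present: {genes}")
    if missing:
        logger.warning("signature genes missing from matrix: %s", missing)
    sub = expr.loc[present].astype(float)
    if log_scale:
        sub = np.log2(sub + 1.0)
    score = sub.mean(axis=0)
    score.name = "ifng_score"
    return score


# ---------------------------------------------------------------------------
# Tukey fences and the burden-activity fit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuartileSummary:
    q1: float
    q2: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def lower_fence(self) -> float:
        return self.q1 - 1.5 * self.iqr

    @property
    def upper_fence(self) -> float:
        return self.q3 + 1.5 * self.iqr


def tukey_outliers(values) -> tuple[np.ndarray, np.ndarray, QuartileSummary]:
    """Remove values strictly outside the Tukey fences.

    Quartiles use linear interpolation between order statistics.  Returns
    (kept values, outlier indices into the input, quartile summary).
    Requires at least four observations.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise DataError("Tukey outlier removal needs at least 4 values")
    q1, q2, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    summary = QuartileSummary(float(q1), float(q2), float(q3))
    out_mask = (v < summary.lower_fence) | (v > summary.upper_fence)
    return v[~out_mask], np.flatnonzero(out_mask), summary


@dataclass(frozen=True)
class BurdenActivityFit:
    r2: float
    p_value: float
    slope: float
    intercept: float
    n_used: int


def burden_activity_fit(
    burden, activity, activity_floor: float = 0.5
) -> BurdenActivityFit:
    """OLS of mutation burden on signature activity.

    Restricted to samples with activity >= ``activity_floor``; burden
    outliers by the Tukey rule are then removed before fitting.  Reports
    the model R², the F-test p-value, and the coefficients.
    """
    burden = np.asarray(burden, dtype=float)
    activity = np.asarray(activity, dtype=float)
    if burden.shape != activity.shape:
        raise DataError("burden and activity must be paired vectors")
    mask = activity >= activity_floor
    if not mask.any():
        raise DataError(f"no samples with activity >= {activity_floor}")
    b, a = burden[mask], activity[mask]
    _, out_idx, _ = tukey_outliers(b)
    keep = np.ones(b.size, dtype=bool)
    keep[out_idx] = False
    b, a = b[keep], a[keep]
    if b.size < 3:
        raise DataError("fewer than 3 samples left for the burden-activity fit")
    model = sm.OLS(b, sm.add_constant(a)).fit()
    return BurdenActivityFit(
        r2=float(model.rsquared),
        p_value=float(model.f_pvalue) if b.size > 2 else float("nan"),
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        n_used=int(b.size),
    )
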