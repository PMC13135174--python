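"""Nonparametric group comparisons and DeLong AUC inference.

The rank tests wrap the vetted SciPy routines (midranks, tie-corrected
variances, continuity correction for the normal approximation of U; the
Mann-Whitney test switches to exact enumeration for small tie-free
samples). The DeLong machinery — AUC variance and covariance from
structural components — is implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sstats


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def shapiro_gate(values) -> TestResult:
    """Shapiro-Wilk normality test (gate for the nonparametric tests)."""
    values = np.asarray(values, dtype=float)
    if not 3 <= values.size <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {values.size}")
    if np.ptp(values) == 0:
        raise ValueError("constant sample: normality undefined")
    stat, p = sstats.shapiro(values)
    return TestResult(float(stat), float(p), "shapiro-wilk", (values.size,))


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U.

    Exact enumeration when both sides have <= 8 tie-free observations,
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and not ties) else "asymptotic"
    res = sstats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return TestResult(
        float(res.statistic), float(res.pvalue), f"mann-whitney-u/{method}",
        (x.size, y.size),
    )


def kruskal_wallis(groups: Sequence) -> TestResult:
    """Kruskal-Wallis H with tie correction; chi-square p on k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return TestResult(0.0, 1.0, "kruskal-wallis", tuple(g.size for g in groups))
    stat, p = sstats.kruskal(*groups)
    return TestResult(float(stat), float(p), "kruskal-wallis", tuple(g.size for g in groups))


# --- DeLong structural components -----------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return sstats.rankdata(x, method="average")


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """Per-observation placement values and the AUC for one score vector."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (np.sum(all_ranks[:m]) - m * (m + 1) / 2.0) / (m * n)
    v_pos = (all_ranks[:m] - pos_ranks) / n          # V10 components
    v_neg = 1.0 - (all_ranks[m:] - neg_ranks) / m    # V01 components
    return auc, v_pos, v_neg


def delong_auc_variance(scores, labels) -> tuple:
    """(AUC, variance) for a single score vector via DeLong components."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    auc, v_pos, v_neg = _structural_components(scores, labels)
    m, n = v_pos.size, v_neg.size
    var = _var(v_pos) / m + _var(v_neg) / n
    return float(auc), float(var)


def _var(v: np.ndarray) -> float:
    return float(np.var(v, ddof=1)) if v.size > 1 else 0.0


def _cov(a: np.ndarray, b: np.ndarray) -> float:
    if a.size <= 1:
        return 0.0
    return float(np.cov(a, b, ddof=1)[0, 1])


def delong_auc_test(scores_a, scores_b, labels) -> TestResult:
    """Paired DeLong comparison of two AUCs on the same observations."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("scores_a, scores_b and labels must share a shape")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    auc_a, vp_a, vn_a = _structural_components(scores_a, labels)
    auc_b, vp_b, vn_b = _structural_components(scores_b, labels)
    m, n = vp_a.size, vn_a.size
    var_diff = (
        (_var(vp_a) + _var(vp_b) - 2 * _cov(vp_a, vp_b)) / m
        + (_var(vn_a) + _var(vn_b) - 2 * _cov(vn_a, vn_b)) / n
    )
    diff = auc_a - auc_b
    if var_diff <= 0:
        # identical (or perfectly coupled) scores: exact equality
        z, p = 0.0, 1.0
        if abs(diff) > 0:
            z, p = np.inf * np.sign(diff), 0.0
    else:
        z = diff / np.sqrt(var_diff)
        p = 2.0 * sstats.norm.sf(abs(z))
    return TestResult(float(z), float(p), "delong", (m, n))


def delong_auc_ci(scores, labels, alpha: float = 0.05) -> tuple:
    """(AUC, (lo, hi)) Wald interval from the DeLong variance, clipped to [0, 1]."""
    auc, var = delong_auc_variance(scores, labels)
    half = sstats.norm.ppf(1.0 - alpha / 2.0) * np.sqrt(max(var, 0.0))
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def auc_mann_whitney(scores, labels) -> float:
    """AUC via the U/(n1*n2) identity (independent check of the DeLong AUC)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    u = sstats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (pos.size * neg.size))
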