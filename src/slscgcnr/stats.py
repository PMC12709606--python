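"""Diagnostic-accuracy and inter-reader agreement statistics.

Implements the statistics used to evaluate fluid vs solid mass
classification: empirical ROC curves with trapezoidal AUC, percentile
bootstrap confidence intervals, the lower-bound AUC of a single
operating point, DeLong's paired test for correlated AUCs, and Fleiss'
kappa with its large-sample null variance, z-score, two-sided P value
and the conventional verbal interpretation bands.

Conventions: scores are gCNR values in [0, 1]; labels are binary with
1 = fluid (positive) and 0 = solid (negative); a mass is called
positive when its score is at or above the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "ROCResult",
    "KappaResult",
    "DelongResult",
    "roc_curve",
    "auc_trapezoid",
    "mann_whitney_auc",
    "bootstrap_auc_ci",
    "lower_bound_auc",
    "bootstrap_reader_mean_auc",
    "delong_test",
    "fleiss_kappa",
    "kappa_band",
    "kappa_difference_test",
]

_MIN_P = 1e-16


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D arrays")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary (1 = fluid, 0 = solid)")
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ValueError("both classes must be present")
    return scores, labels


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC curve and its trapezoidal area."""

    thresholds: np.ndarray
    sens: np.ndarray
    one_minus_spec: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    ci: tuple[float, float] | None = None


def roc_curve(scores, labels, thresholds=None) -> ROCResult:
    """Empirical ROC with the tie rule score >= threshold -> fluid call.

    ``thresholds`` defaults to the observed score values plus 0 and 1
    (the exact empirical ROC). Sensitivity is TP/(TP+FN) over fluid
    masses; specificity TN/(TN+FP) over solid masses. The curve always
    includes the endpoints (0,0) and (1,1).
    """
    scores, labels = _check_scores_labels(scores, labels)
    if thresholds is None:
        thresholds = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    else:
        thresholds = np.sort(np.asarray(thresholds, dtype=float))
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    sens = (pos[None, :] >= thresholds[:, None]).mean(axis=1)
    fpr = (neg[None, :] >= thresholds[:, None]).mean(axis=1)
    # Endpoints: a threshold above every score gives (0,0); one at or
    # below every score gives (1,1).
    fpr_all = np.concatenate([[1.0], fpr, [0.0]])
    sens_all = np.concatenate([[1.0], sens, [0.0]])
    auc = auc_trapezoid(fpr_all, sens_all)
    return ROCResult(
        thresholds=thresholds,
        sens=sens,
        one_minus_spec=fpr,
        auc=auc,
        n_pos=pos.size,
        n_neg=neg.size,
    )


def auc_trapezoid(one_minus_spec, sens) -> float:
    """Trapezoidal area under ROC points; duplicate x-values add zero width.

    Points are sorted internally by (1-specificity, sensitivity).
    """
    x = np.asarray(one_minus_spec, dtype=float)
    y = np.asarray(sens, dtype=float)
    order = np.lexsort((y, x))
    return float(np.trapezoid(y[order], x[order]))


def mann_whitney_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney statistic with ties counted 1/2.

    Equals the trapezoidal area of the exact empirical ROC; used as the
    fast inner estimator for bootstrap resampling.
    """
    scores, labels = _check_scores_labels(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def bootstrap_auc_ci(
    scores,
    labels,
    n_iter: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC.

    (score, label) pairs are resampled jointly with replacement;
    resamples that lose a class are redrawn.
    """
    scores, labels = _check_scores_labels(scores, labels)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    n = scores.size
    aucs = np.empty(n_iter)
    for b in range(n_iter):
        while True:
            idx = rng.integers(0, n, n)
            lab = labels[idx]
            if 0 < lab.sum() < n:
                break
        aucs[b] = mann_whitney_auc(scores[idx], lab)
    lo, hi = np.percentile(aucs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def lower_bound_auc(sens: float, spec: float) -> float:
    """Area of the two-segment ROC through one operating point.

    The trapezoid through (0,0) -> (1-spec, sens) -> (1,1) integrates
    to (sens + spec) / 2.
    """
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ValueError("sens and spec must be in [0, 1]")
    return (sens + spec) / 2.0


def bootstrap_reader_mean_auc(
    points,
    n_iter: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """Mean lower-bound AUC over readers with a percentile bootstrap CI.

    ``points`` is a sequence of per-reader (sens, spec) operating
    points; each iteration resamples readers with replacement
    (duplicates allowed) and averages their lower-bound AUCs.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("points must be an (n_readers >= 2, 2) array of (sens, spec)")
    lb = np.array([lower_bound_auc(s, p) for s, p in pts])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, lb.size, (n_iter, lb.size))
    means = lb[idx].mean(axis=1)
    lo, hi = np.percentile(means, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lb.mean()), float(lo), float(hi)


@dataclass(frozen=True)
class DelongResult:
    auc_a: float
    auc_b: float
    delta: float
    z: float
    p_value: float
    degenerate: bool = False


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong structural components (placement values)."""
    x = scores[labels == 1]
    y = scores[labels == 0]
    # psi(X_i, Y_j) = 1 if X > Y, 1/2 if tied, 0 otherwise
    cmp = (x[:, None] > y[None, :]).astype(float) + 0.5 * (x[:, None] == y[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return float(cmp.mean()), v10, v01


def delong_test(scores_a, scores_b, labels) -> DelongResult:
    """DeLong's paired test for the difference of two correlated AUCs.

    Both score sets must rate the same masses against the same truth
    labels; binary reader calls are accepted as two-valued scores. The
    two-sided P value comes from the normal approximation on
    ``(auc_a - auc_b) / sqrt(var(delta))`` with the variance built from
    paired placement-value structural components.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("scores_a and scores_b must rate the same masses")
    _, labels = _check_scores_labels(scores_a, labels)
    auc_a, v10_a, v01_a = _placements(scores_a, labels)
    auc_b, v10_b, v01_b = _placements(scores_b, labels)
    m, n = v10_a.size, v01_a.size
    delta = auc_a - auc_b
    if m < 2 or n < 2:
        raise ValueError("DeLong's test needs >= 2 masses in each class")
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        if delta == 0:
            return DelongResult(auc_a, auc_b, 0.0, 0.0, 1.0, degenerate=False)
        return DelongResult(auc_a, auc_b, delta, math.inf, _MIN_P, degenerate=True)
    z = delta / math.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return DelongResult(auc_a, auc_b, delta, float(z), float(max(p, _MIN_P)))


_KAPPA_BANDS = (
    (0.0, "poor"),  # kappa < 0
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
)


def kappa_band(kappa: float) -> str:
    """Verbal interpretation band for a kappa value.

    poor (< 0), slight (0-0.20), fair (0.21-0.40), moderate
    (0.41-0.60), substantial (0.61-0.80), perfect (above 0.80).
    """
    if kappa < 0.0:
        return "poor"
    for hi, name in _KAPPA_BANDS[1:]:
        if kappa <= hi:
            return name
    return "perfect"


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    variance: float
    z: float
    p_value: float
    band: str
    p_bar: float
    p_e: float
    n_subjects: int
    n_raters: int
    degenerate: bool = False


def _ratings_to_counts(ratings: np.ndarray, categories=None) -> np.ndarray:
    ratings = np.asarray(ratings)
    if ratings.ndim != 2:
        raise ValueError("ratings must be (n_subjects, n_raters)")
    if categories is None:
        categories = np.unique(ratings)
    counts = np.stack([(ratings == c).sum(axis=1) for c in categories], axis=1)
    return counts


def fleiss_kappa(
    ratings,
    categories=None,
    counts: bool = False,
    variance_method: str = "fnl",
) -> KappaResult:
    """Fleiss' kappa for multiple raters with large-sample significance.

    Parameters
    ----------
    ratings:
        Either an ``(n_subjects, n_raters)`` matrix of categorical
        labels, or (with ``counts=True``) an ``(n_subjects,
        n_categories)`` matrix of rating counts. Every subject must be
        rated by the same number of raters (>= 2).
    categories:
        Explicit category list (label matrices only); defaults to the
        observed labels. Categories never used still contribute zero
        columns when listed.
    variance_method:
        ``"fnl"`` (Fleiss-Nee-Landis large-sample null variance,
        default) or ``"fleiss"`` (the original large-sample formula).
        Both test the null hypothesis kappa = 0.

    Notes
    -----
    kappa = (P_bar - P_e) / (1 - P_e) where P_bar is the mean observed
    pairwise agreement and P_e = sum_j p_j^2 the chance agreement. When
    every rating falls in one category P_e = 1 and kappa is undefined;
    it is reported as 1 with ``degenerate=True``.
    """
    table = np.asarray(ratings) if counts else _ratings_to_counts(ratings, categories)
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 1:
        raise ValueError("need a 2-D table with at least one subject")
    n_per = table.sum(axis=1)
    if not np.all(n_per == n_per[0]):
        raise ValueError("every subject must be rated by the same number of raters")
    n = int(n_per[0])
    if n < 2:
        raise ValueError("at least 2 raters per subject are required")
    n_subj = table.shape[0]

    p_j = table.sum(axis=0) / (n_subj * n)
    p_i = ((table**2).sum(axis=1) - n) / (n * (n - 1))
    p_bar = float(p_i.mean())
    p_e = float((p_j**2).sum())

    if p_e >= 1.0 - 1e-12:
        return KappaResult(
            kappa=1.0, variance=0.0, z=math.nan, p_value=1.0, band="perfect",
            p_bar=p_bar, p_e=p_e, n_subjects=n_subj, n_raters=n, degenerate=True,
        )

    kappa = (p_bar - p_e) / (1.0 - p_e)
    q_j = 1.0 - p_j
    if variance_method == "fnl":
        s = float((p_j * q_j).sum())
        var = (2.0 / (n_subj * n * (n - 1))) * (s**2 - float((p_j * q_j * (q_j - p_j)).sum())) / s**2
    elif variance_method == "fleiss":
        var = (
            (2.0 / (n_subj * n * (n - 1)))
            * (p_e - (2 * n - 3) * p_e**2 + 2 * (n - 2) * float((p_j**3).sum()))
            / (1.0 - p_e) ** 2
        )
    else:
        raise ValueError("variance_method must be 'fnl' or 'fleiss'")
    if var <= 0:
        z = math.inf if kappa > 0 else (-math.inf if kappa < 0 else 0.0)
        p = 1.0 if kappa == 0 else _MIN_P
    else:
        z = kappa / math.sqrt(var)
        p = float(max(2.0 * norm.sf(abs(z)), _MIN_P))
    return KappaResult(
        kappa=float(kappa), variance=float(var), z=float(z), p_value=p,
        band=kappa_band(float(kappa)), p_bar=p_bar, p_e=p_e,
        n_subjects=n_subj, n_raters=n,
    )


def kappa_difference_test(result_a: KappaResult, result_b: KappaResult) -> tuple[float, float, float]:
    """Two-sided z-test on the difference of two kappa values.

    Variances are added as if the two panels were independent — the
    large-sample null model provides no covariance for paired panels,
    so this is an approximation (flagged in the study report).
    Returns ``(delta, z, p)``.
    """
    delta = result_a.kappa - result_b.kappa
    var = result_a.variance + result_b.variance
    if var <= 0:
        return (delta, 0.0 if delta == 0 else math.inf, 1.0 if delta == 0 else _MIN_P)
    z = delta / math.sqrt(var)
    p = float(max(2.0 * norm.sf(abs(z)), _MIN_P))
    return (float(delta), float(z), p)
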