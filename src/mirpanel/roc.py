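"""ROC/AUC machinery with DeLong inference, confusion-matrix metrics, and
predictive values.

The AUC and its variance use the DeLong structural-component construction
with midranks, so ties are handled exactly (a tied case-control pair
contributes 1/2). The paired test compares two correlated AUCs computed on
the same samples — the situation that arises when nested discriminant
models are scored on one discovery set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ROCResult",
    "ConfusionMetrics",
    "auc_with_delong",
    "delong_paired_test",
    "roc_points",
    "confusion_at_cutoff",
    "compare_accuracy_chi2",
    "predictive_values",
    "baseline_balance_tests",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class ROCResult:
    """AUC with a DeLong 95% CI and the full ROC polyline.

    ``curve`` is an array of (1 - specificity, sensitivity) points over all
    distinct thresholds, from (0,0) to (1,1); its trapezoidal area equals
    ``auc`` exactly (midrank construction).
    """

    auc: float
    auc_ci: tuple[float, float]
    curve: np.ndarray
    variance: float


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    accuracy_ci: tuple[float, float]

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _structural_components(
    case_scores: np.ndarray, control_scores: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus per-observation DeLong components via midranks.

    V10[i] = mean_j psi(case_i, control_j), V01[j] = mean_i psi(case_i,
    control_j), psi = 1 / 0.5 / 0 for > / = / <.
    """
    x = np.asarray(case_scores, float)
    y = np.asarray(control_scores, float)
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("each class needs at least one score")
    all_scores = np.concatenate([x, y])
    r_all = stats.rankdata(all_scores)  # midranks
    r_x = stats.rankdata(x)
    r_y = stats.rankdata(y)
    v10 = (r_all[:m] - r_x) / n
    v01 = 1.0 - (r_all[m:] - r_y) / m
    auc = float(v10.mean())
    return auc, v10, v01


def _component_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    s10 = float(np.var(v10, ddof=1)) if len(v10) > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if len(v01) > 1 else 0.0
    return s10 / len(v10) + s01 / len(v01)


def roc_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """(1 - specificity, sensitivity) over all distinct thresholds,
    prepended with (0,0); positive iff score >= threshold."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    distinct = np.flatnonzero(np.diff(s) != 0)
    cut = np.concatenate([distinct, [len(s) - 1]])
    tp = np.cumsum(y)[cut]
    fp = np.cumsum(~y)[cut]
    tpr = np.concatenate([[0.0], tp / max(labels.sum(), 1)])
    fpr = np.concatenate([[0.0], fp / max((~labels).sum(), 1)])
    return np.column_stack([fpr, tpr])


def auc_with_delong(
    scores_case: np.ndarray, scores_control: np.ndarray
) -> ROCResult:
    """AUC (midrank/Mann-Whitney), DeLong variance, normal 95% CI clipped
    to [0, 1], and the ROC polyline."""
    auc, v10, v01 = _structural_components(scores_case, scores_control)
    var = _component_variance(v10, v01)
    half = Z95 * math.sqrt(max(var, 0.0))
    ci = (max(auc - half, 0.0), min(auc + half, 1.0))
    scores = np.concatenate([scores_case, scores_control])
    labels = np.concatenate(
        [np.ones(len(scores_case), bool), np.zeros(len(scores_control), bool)]
    )
    return ROCResult(auc=auc, auc_ci=ci, curve=roc_points(scores, labels), variance=var)


def delong_paired_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float, float]:
    """DeLong's test for two correlated AUCs on the same samples.

    Returns (auc_a, auc_b, z, two-sided p). With zero variance of the
    difference (e.g. identical or rank-equivalent scores), p = 1 when the
    AUCs agree and 0 when they differ exactly.
    """
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    labels = np.asarray(labels, bool)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("score vectors and labels must have equal length")
    auc_a, v10_a, v01_a = _structural_components(scores_a[labels], scores_a[~labels])
    auc_b, v10_b, v01_b = _structural_components(scores_b[labels], scores_b[~labels])
    m, n = len(v10_a), len(v01_a)
    var_a = _component_variance(v10_a, v01_a)
    var_b = _component_variance(v10_b, v01_b)
    if m > 1:
        cov10 = float(np.cov(v10_a, v10_b, ddof=1)[0, 1])
    else:
        cov10 = 0.0
    if n > 1:
        cov01 = float(np.cov(v01_a, v01_b, ddof=1)[0, 1])
    else:
        cov01 = 0.0
    cov = cov10 / m + cov01 / n
    var_diff = var_a + var_b - 2.0 * cov
    if var_diff <= 1e-15:
        if abs(auc_a - auc_b) < 1e-12:
            return auc_a, auc_b, 0.0, 1.0
        z = math.inf if auc_a > auc_b else -math.inf
        return auc_a, auc_b, z, 0.0
    z = (auc_a - auc_b) / math.sqrt(var_diff)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return auc_a, auc_b, float(z), p


def _wald_ci(p: float, n: int) -> tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    half = Z95 * math.sqrt(p * (1.0 - p) / n)
    return (max(p - half, 0.0), min(p + half, 1.0))


def confusion_at_cutoff(
    scores: np.ndarray, labels: np.ndarray, cutoff: float = 0.0
) -> ConfusionMetrics:
    """Confusion counts and Wald 95% CIs at a fixed cutoff (>= is positive)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be nonempty")
    pos = scores >= cutoff
    tp = int((pos & labels).sum())
    fp = int((pos & ~labels).sum())
    tn = int((~pos & ~labels).sum())
    fn = int((~pos & labels).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / len(labels)
    return ConfusionMetrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        sensitivity_ci=_wald_ci(sens, tp + fn),
        specificity_ci=_wald_ci(spec, tn + fp),
        accuracy_ci=_wald_ci(acc, len(labels)),
    )


def compare_accuracy_chi2(
    correct_a: int, n_a: int, correct_b: int, n_b: int
) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2 table
    correct/incorrect x model."""
    if correct_a > n_a or correct_b > n_b:
        raise ValueError("correct counts cannot exceed totals")
    table = np.array(
        [[correct_a, n_a - correct_a], [correct_b, n_b - correct_b]], float
    )
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    if (row == 0).any() or (col == 0).any():
        warnings.warn("degenerate 2x2 table (zero margin); p = 1", stacklevel=2)
        return 0.0, 1.0
    expected = np.outer(row, col) / n
    chi2 = float(((table - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def predictive_values(
    sensitivity: float, specificity: float, prevalence: float
) -> tuple[float, float]:
    """PPV and NPV of a test at a given disease prevalence (Bayes).

    An undefined value (zero denominator) is returned as NaN with a warning.
    """
    for name, v in (
        ("sensitivity", sensitivity),
        ("specificity", specificity),
        ("prevalence", prevalence),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    p = prevalence
    ppv_den = sensitivity * p + (1.0 - specificity) * (1.0 - p)
    npv_den = specificity * (1.0 - p) + (1.0 - sensitivity) * p
    if ppv_den == 0.0:
        warnings.warn("PPV undefined (no positive tests expected)", stacklevel=2)
        ppv = math.nan
    else:
        ppv = sensitivity * p / ppv_den
    if npv_den == 0.0:
        warnings.warn("NPV undefined (no negative tests expected)", stacklevel=2)
        npv = math.nan
    else:
        npv = specificity * (1.0 - p) / npv_den
    return ppv, npv


def baseline_balance_tests(table_a, table_b) -> dict[str, float]:
    """Covariate balance between two sample tables (e.g. discovery vs
    validation arms): two-sample pooled-variance t-test for age, Pearson
    chi-square for the categorical covariates.

    For stage, histology, and control_source the placeholder level ``none``
    is excluded (it marks non-applicability, not a category). Levels empty
    in both tables are dropped with a warning.
    """
    if len(table_a.df) == 0 or len(table_b.df) == 0:
        raise ValueError("both tables must be nonempty")
    out: dict[str, float] = {}
    age_a = table_a.df["age"].to_numpy(float)
    age_b = table_b.df["age"].to_numpy(float)
    t, p = stats.ttest_ind(age_a, age_b, equal_var=True)
    if math.isnan(p):  # zero pooled variance
        p = 1.0 if age_a.mean() == age_b.mean() else 0.0
    out["age"] = float(p)
    for col in ("gender", "stage", "histology", "control_source"):
        a = table_a.df[col]
        b = table_b.df[col]
        if col != "gender":
            a = a[a != "none"]
            b = b[b != "none"]
        levels = sorted(set(a.unique()) | set(b.unique()))
        counts = np.array(
            [[(a == lv).sum() for lv in levels], [(b == lv).sum() for lv in levels]],
            float,
        )
        empty = counts.sum(axis=0) == 0
        if empty.any():
            warnings.warn(f"dropping empty {col} level(s)", stacklevel=2)
            counts = counts[:, ~empty]
        if counts.shape[1] < 2 or (counts.sum(axis=1) == 0).any():
            out[col] = 1.0
            continue
        chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
        out[col] = float(p)
    return out
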