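"""Fisher linear discriminant fitting, leave-one-out cross-validation,
greedy forward panel search, Youden recentring, and model-size selection.

The discriminant direction is w = S_pooled^-1 (mu_case - mu_control) with
the pooled within-class covariance on n - 2 degrees of freedom; the
midpoint intercept -w . (mu_case + mu_control)/2 centres the boundary
between the class means. Panels grow strictly forward: the size-k panel is
the size-(k-1) panel plus the candidate that maximizes LOOCV accuracy,
with ties broken by higher in-sample AUC and then by lexicographic miRNA
id, so the search is deterministic.

LOOCV refits the discriminant for every held-out sample. The hot path
(``_loocv_scores``) expresses each leave-one-out fit as a rank-one downdate
of the class mean and scatter and solves all n systems in one stacked
``np.linalg.solve`` call; an explicit per-sample refit loop with the same
contract lives in the test suite as the independent oracle.

Model-size selection follows the study design: prefer the largest panel
whose AUC significantly beats the next-smaller panel (paired DeLong) while
the next-larger panel adds nothing significant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import ExpressionMatrix, LinearDiscriminantModel
from .roc import (
    ROCResult,
    auc_with_delong,
    compare_accuracy_chi2,
    confusion_at_cutoff,
    delong_paired_test,
)

__all__ = [
    "TraceRow",
    "GreedySearchTrace",
    "fit_fisher_lda",
    "loocv_metrics",
    "greedy_search",
    "recenter_youden",
    "youden_threshold",
    "select_model_size",
]

logger = logging.getLogger(__name__)

RIDGE_EPS = 1e-8


def _as_feature_array(features, panel=None) -> np.ndarray:
    """Samples-x-features float array from an ExpressionMatrix (optionally
    restricted to a panel, in panel order) or a plain array."""
    if isinstance(features, ExpressionMatrix):
        data = features.data if panel is None else features.data.loc[list(panel)]
        return data.to_numpy().T.astype(float)
    X = np.asarray(features, float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def _pooled_fit(X: np.ndarray, y: np.ndarray):
    """Class means, pooled scatter, and the solved direction w."""
    n, p = X.shape
    n1 = int(y.sum())
    n0 = n - n1
    if n1 < 2 or n0 < 2:
        raise ValueError("each class needs at least 2 samples")
    mu1 = X[y].mean(axis=0)
    mu0 = X[~y].mean(axis=0)
    d1 = X[y] - mu1
    d0 = X[~y] - mu0
    scatter = d1.T @ d1 + d0.T @ d0
    s_pooled = scatter / (n - 2)
    w = _solve_spd(s_pooled, mu1 - mu0)
    return mu1, mu0, scatter, w


def _solve_spd(s: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Solve S w = d; on a singular S, retry with a small ridge
    (eps * trace(S)/p on the diagonal) and log a warning."""
    try:
        return np.linalg.solve(s, d)
    except np.linalg.LinAlgError:
        p = s.shape[-1]
        ridge = RIDGE_EPS * np.trace(s) / p
        if ridge == 0:
            ridge = RIDGE_EPS
        logger.warning("singular pooled covariance; adding ridge %.3e", ridge)
        return np.linalg.solve(s + ridge * np.eye(p), d)


def fit_fisher_lda(features, labels, panel=None) -> LinearDiscriminantModel:
    """Two-class Fisher discriminant with the midpoint intercept.

    ``features`` is an ExpressionMatrix on the log2 scale (restricted to
    ``panel``) or a samples-x-features array; ``labels`` is the boolean case
    indicator. Cases score higher on average.
    """
    X = _as_feature_array(features, panel)
    y = np.asarray(labels, bool)
    mu1, mu0, _, w = _pooled_fit(X, y)
    intercept = -float(w @ (mu1 + mu0)) / 2.0
    if isinstance(features, ExpressionMatrix):
        ids = list(panel) if panel is not None else features.mirna_ids
        scale = features.scale
    else:
        ids = [f"f{j}" for j in range(X.shape[1])] if panel is None else list(panel)
        scale = "log2"
    return LinearDiscriminantModel(
        mirna_ids=ids,
        coefficients=w,
        intercept=intercept,
        cutoff=0.0,
        feature_scale=scale,
    )


def _loocv_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Leave-one-out discriminant score of each sample under the model
    refit on the remaining n-1 (midpoint intercept, cutoff 0).

    Each held-out fit is the full fit with the held-out sample removed from
    its class mean and scatter (rank-one downdate); all n solves run as one
    stacked linear solve.
    """
    n, p = X.shape
    y = np.asarray(y, bool)
    n1 = int(y.sum())
    n0 = n - n1
    if min(n1, n0) < 2:
        raise ValueError("each class needs at least 2 samples")
    mu1 = X[y].mean(axis=0)
    mu0 = X[~y].mean(axis=0)
    d1 = X[y] - mu1
    d0 = X[~y] - mu0
    scatter = d1.T @ d1 + d0.T @ d0

    mu_own = np.where(y[:, None], mu1[None, :], mu0[None, :])
    n_own = np.where(y, n1, n0).astype(float)
    u = X - mu_own  # deviation from own class mean
    # class mean without sample i
    mu_own_loo = (n_own[:, None] * mu_own - X) / (n_own - 1)[:, None]
    mu_other = np.where(y[:, None], mu0[None, :], mu1[None, :])
    # scatter without sample i: rank-one downdate of the own-class scatter
    shrink = (n_own / (n_own - 1))[:, None, None]
    s_loo = scatter[None, :, :] - shrink * (u[:, :, None] * u[:, None, :])
    s_loo /= (n - 3)
    sign = np.where(y, 1.0, -1.0)  # d = mu_case - mu_control
    d = sign[:, None] * (mu_own_loo - mu_other)
    try:
        w = np.linalg.solve(s_loo, d[..., None])[..., 0]
    except np.linalg.LinAlgError:
        tr = np.trace(s_loo, axis1=1, axis2=2)
        ridge = RIDGE_EPS * tr / p
        ridge = np.where(ridge == 0, RIDGE_EPS, ridge)
        logger.warning("singular LOOCV pooled covariance; adding ridge")
        s_loo = s_loo + ridge[:, None, None] * np.eye(p)[None, :, :]
        w = np.linalg.solve(s_loo, d[..., None])[..., 0]
    midpoint = (mu_own_loo + mu_other) / 2.0
    return np.einsum("ij,ij->i", w, X - midpoint)


def loocv_metrics(features, labels, panel=None) -> tuple[float, float, float]:
    """LOOCV (sensitivity, specificity, accuracy) at the midpoint cutoff 0."""
    X = _as_feature_array(features, panel)
    y = np.asarray(labels, bool)
    scores = _loocv_scores(X, y)
    pred = scores >= 0.0
    sens = float((pred & y).sum() / y.sum())
    spec = float((~pred & ~y).sum() / (~y).sum())
    acc = float((pred == y).mean())
    return sens, spec, acc


@dataclass
class TraceRow:
    """One panel size of the greedy search (one row of the combinations
    table): the chosen panel, its fitted model, LOOCV metrics with Wald CIs,
    in-sample AUC with DeLong CI, and nested-comparison p-values against the
    previous size."""

    k: int
    mirna_ids: list[str]
    model: LinearDiscriminantModel
    sensitivity: float
    specificity: float
    accuracy: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    accuracy_ci: tuple[float, float]
    auc: float
    auc_ci: tuple[float, float]
    p_accuracy_vs_prev: float | None
    p_auc_vs_prev: float | None
    loocv_correct: int
    n: int
    insample_scores: np.ndarray = field(repr=False)


@dataclass
class GreedySearchTrace:
    rows: list[TraceRow]
    selected_k: int | None = None

    def row(self, k: int) -> TraceRow:
        for r in self.rows:
            if r.k == k:
                return r
        raise KeyError(f"no panel of size {k} in trace")

    @property
    def k_max(self) -> int:
        return max(r.k for r in self.rows)

    def selected_model(self) -> LinearDiscriminantModel:
        if self.selected_k is None:
            raise ValueError("no model size selected yet")
        return self.row(self.selected_k).model


def _panel_stats(X: np.ndarray, y: np.ndarray):
    """(loocv_acc, insample_auc, loocv_scores, insample_scores) for a panel."""
    loocv = _loocv_scores(X, y)
    model_scores = _insample_scores(X, y)
    auc, _, _ = _auc_only(model_scores, y)
    acc = float(((loocv >= 0) == y).mean())
    return acc, auc, loocv, model_scores


def _insample_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    mu1, mu0, _, w = _pooled_fit(X, y)
    return X @ w - float(w @ (mu1 + mu0)) / 2.0


def _auc_only(scores: np.ndarray, y: np.ndarray):
    from .roc import _structural_components

    return _structural_components(scores[y], scores[~y])


def greedy_search(
    features,
    labels,
    candidate_ids,
    k_max: int = 5,
    alpha: float = 0.05,
    select: bool = True,
) -> GreedySearchTrace:
    """Greedy forward panel search driven by LOOCV accuracy.

    At each size the candidate maximizing the LOOCV accuracy of the enlarged
    panel joins; ties break toward higher in-sample AUC, then lexicographic
    miRNA id. Each row records LOOCV metrics (Wald CIs), in-sample AUC
    (DeLong CI), and, against the previous size, a Pearson chi-square
    p-value on LOOCV accuracy and a paired DeLong p-value on AUC. When
    ``select`` is true the trace's ``selected_k`` is filled via
    :func:`select_model_size`.
    """
    if isinstance(features, ExpressionMatrix):
        if features.scale != "log2":
            raise ValueError("greedy_search expects log2-scale features")
        missing = [c for c in candidate_ids if c not in features.data.index]
        if missing:
            raise KeyError(f"candidate miRNA(s) absent: {missing[:5]}")
        full = features.data.loc[list(candidate_ids)].to_numpy().T.astype(float)
    else:
        full = np.asarray(features, float)
    candidate_ids = list(candidate_ids)
    if len(set(candidate_ids)) != len(candidate_ids):
        raise ValueError("duplicate candidate ids")
    y = np.asarray(labels, bool)
    n = len(y)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if k_max > len(candidate_ids):
        warnings.warn(
            f"k_max {k_max} exceeds {len(candidate_ids)} candidates; truncating",
            stacklevel=2,
        )
        k_max = len(candidate_ids)

    col = {m: j for j, m in enumerate(candidate_ids)}
    panel: list[str] = []
    rows: list[TraceRow] = []
    prev_scores: np.ndarray | None = None
    prev_correct: int | None = None

    for k in range(1, k_max + 1):
        best = None  # (acc, auc, id, loocv_scores, insample_scores)
        base_cols = [col[m] for m in panel]
        for cand in candidate_ids:
            if cand in panel:
                continue
            X = full[:, base_cols + [col[cand]]]
            acc, auc, loocv, insample = _panel_stats(X, y)
            key = (acc, auc)
            if best is None or key > best[:2] or (key == best[:2] and cand < best[2]):
                best = (acc, auc, cand, loocv, insample)
        acc, _, chosen, loocv, insample = best
        panel = panel + [chosen]
        logger.info("size %d panel: %s (LOOCV accuracy %.4f)", k, panel, acc)

        X = full[:, [col[m] for m in panel]]
        model = _fit_with_ids(X, y, panel)
        cm = confusion_at_cutoff(loocv, y, 0.0)
        roc = auc_with_delong(insample[y], insample[~y])
        correct = cm.tp + cm.tn
        p_acc = p_auc = None
        if prev_scores is not None:
            _, p_acc = compare_accuracy_chi2(correct, n, prev_correct, n)
            _, _, _, p_auc = delong_paired_test(insample, prev_scores, y)
        rows.append(
            TraceRow(
                k=k,
                mirna_ids=list(panel),
                model=model,
                sensitivity=cm.sensitivity,
                specificity=cm.specificity,
                accuracy=cm.accuracy,
                sensitivity_ci=cm.sensitivity_ci,
                specificity_ci=cm.specificity_ci,
                accuracy_ci=cm.accuracy_ci,
                auc=roc.auc,
                auc_ci=roc.auc_ci,
                p_accuracy_vs_prev=p_acc,
                p_auc_vs_prev=p_auc,
                loocv_correct=correct,
                n=n,
                insample_scores=insample,
            )
        )
        prev_scores = insample
        prev_correct = correct

    trace = GreedySearchTrace(rows=rows)
    if select:
        trace.selected_k = select_model_size(trace, alpha)
    return trace


def _fit_with_ids(X: np.ndarray, y: np.ndarray, ids: list[str]) -> LinearDiscriminantModel:
    mu1, mu0, _, w = _pooled_fit(X, y)
    return LinearDiscriminantModel(
        mirna_ids=list(ids),
        coefficients=w,
        intercept=-float(w @ (mu1 + mu0)) / 2.0,
        cutoff=0.0,
        feature_scale="log2",
    )


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing J = sensitivity + specificity - 1 over the
    observed scores (positive iff score >= t); ties resolve to the smallest
    threshold, which maximizes sensitivity."""
    scores = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be nonempty")
    best_t = None
    best_j = -np.inf
    for t in np.unique(scores):  # ascending, so first max is the smallest t
        sens = float((scores[y] >= t).mean())
        spec = float((scores[~y] < t).mean())
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j = j
            best_t = float(t)
    return best_t


def recenter_youden(
    model: LinearDiscriminantModel, features, labels
) -> LinearDiscriminantModel:
    """Shift the intercept so the Youden-optimal threshold of the training
    scores sits exactly at the cutoff 0."""
    X = _as_feature_array(features, model.mirna_ids)
    scores = X @ model.coefficients + model.intercept
    t = youden_threshold(scores, labels)
    return model.with_intercept(model.intercept - t)


def select_model_size(trace: GreedySearchTrace, alpha: float = 0.05) -> int:
    """Largest panel size k whose AUC significantly beats size k-1 (paired
    DeLong p < alpha) while size k+1 adds nothing significant (p >= alpha
    or k = k_max). Falls back to k = 1 when no size qualifies."""
    ks = sorted(r.k for r in trace.rows)
    p = {k: trace.row(k).p_auc_vs_prev for k in ks if k > min(ks)}
    k_max = max(ks)
    for k in sorted(ks, reverse=True):
        if k == min(ks):
            continue
        if p[k] is not None and p[k] < alpha:
            nxt = k + 1
            if k == k_max or (nxt in p and p[nxt] is not None and p[nxt] >= alpha):
                return k
    return min(ks)
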