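"""End-to-end orchestration: normalize -> filter -> greedy discovery ->
Youden recentring -> validation report, plus the unsupervised summaries
(hierarchical clustering and PCA of the selected panel).

The discovery and validation arms are strictly separated: the normalization
reference level, the filtered candidate list, and the model (coefficients,
intercept, cutoff) are all frozen on discovery samples and applied
unchanged to validation samples.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .core_io import (
    ExpressionMatrix,
    LinearDiscriminantModel,
    SampleTable,
    align,
    apply_index,
    read_expression_matrix,
    read_sample_table,
    write_model,
)
from .lda_search import GreedySearchTrace, greedy_search, recenter_youden
from .preprocess import (
    FilterSpec,
    control_stability,
    fit_normalization,
    log_transform,
    normalize_to_controls,
)
from .roc import (
    ConfusionMetrics,
    ROCResult,
    auc_with_delong,
    confusion_at_cutoff,
    predictive_values,
)

__all__ = [
    "RunConfig",
    "ValidationReport",
    "ClusterSummary",
    "PCASummary",
    "discover",
    "run_discovery",
    "run_validation",
    "cluster_summary",
    "pca_summary",
    "trace_to_frame",
]

logger = logging.getLogger(__name__)

STABILITY_WARN_M = 1.0


@dataclass
class RunConfig:
    """Paths and knobs for a full discovery/validation run."""

    matrix_path: str
    metadata_path: str
    out_dir: str
    control_mirna_ids: tuple[str, str, str] = ("miR-ctl-1", "miR-ctl-2", "miR-ctl-3")
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    k_max: int = 5
    alpha: float = 0.05
    prevalence: float = 0.00742

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")


@dataclass
class ValidationReport:
    """Everything the validation arm reports, all recomputable from the
    per-sample ``index_table`` (sample_id, group, subgroups, index value,
    predicted class)."""

    roc: ROCResult
    confusion: ConfusionMetrics
    specificity_by_source: dict[str, tuple[float, int]]
    sensitivity_by_stage: dict[str, tuple[float, int]]
    sensitivity_by_histology: dict[str, tuple[float, int]]
    ppv: float
    npv: float
    prevalence: float
    index_table: pd.DataFrame


@dataclass
class ClusterSummary:
    leaf_order: list[str]
    assignments: pd.Series
    agreement: float


@dataclass
class PCASummary:
    explained_fractions: np.ndarray
    coordinates: pd.DataFrame  # samples x first <=3 components


def discover(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    control_mirna_ids,
    filter_spec: FilterSpec = FilterSpec(),
    k_max: int = 5,
    alpha: float = 0.05,
):
    """Run the discovery workflow on the ``discovery`` split of a raw cohort.

    Returns (recentred model of the selected size, full greedy trace,
    normalization spec). The model JSON carries the frozen normalization so
    it can be applied to any later cohort.
    """
    matrix = align(matrix, samples)
    disc_samples = samples.split_subset("discovery")
    if len(disc_samples.df) == 0:
        raise ValueError("discovery split is empty; assign splits first")
    disc = matrix.subset_samples(disc_samples.sample_ids)

    stability = control_stability(disc, control_mirna_ids)
    for mid, m in stability.items():
        if m > STABILITY_WARN_M:
            warnings.warn(
                f"control miRNA {mid} has stability M = {m:.2f} > "
                f"{STABILITY_WARN_M}; normalization may be unreliable",
                stacklevel=2,
            )
    logger.info("control stability M: %s", stability.to_dict())

    norm_spec = fit_normalization(disc, control_mirna_ids)
    disc_norm = normalize_to_controls(disc, norm_spec)
    candidates = robust_candidates(disc_norm, disc_samples, filter_spec,
                                   control_mirna_ids)
    logger.info(
        "%d of %d miRNAs pass the robust filter", len(candidates), disc.shape[0]
    )
    if len(candidates) < 2:
        raise ValueError(
            f"only {len(candidates)} candidate(s) survive the robust filter; "
            "relax signal_threshold or sample_fraction"
        )
    feats = log_transform(disc_norm)
    labels = disc_samples.labels(feats.sample_ids)
    trace = greedy_search(feats, labels, candidates, k_max=k_max, alpha=alpha)
    model = trace.selected_model()
    model = recenter_youden(model, feats.subset_mirnas(model.mirna_ids), labels)
    model.normalization = norm_spec
    logger.info(
        "selected %d-miRNA panel %s", trace.selected_k, model.mirna_ids
    )
    return model, trace, norm_spec


def robust_candidates(matrix_norm, samples, filter_spec, control_mirna_ids):
    from .preprocess import robust_filter

    return robust_filter(
        matrix_norm, samples, filter_spec, exclude_ids=control_mirna_ids
    )


def run_discovery(config: RunConfig):
    """File-level wrapper around :func:`discover`: reads the cohort, writes
    model JSON, the per-size combinations table (TSV), and a run log."""
    matrix = read_expression_matrix(config.matrix_path)
    samples = read_sample_table(config.metadata_path)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model, trace, norm_spec = discover(
        matrix,
        samples,
        config.control_mirna_ids,
        config.filter_spec,
        config.k_max,
        config.alpha,
    )
    write_model(model, out / "model.json")
    trace_to_frame(trace).to_csv(out / "combinations.tsv", sep="\t", index=False)
    with open(out / "discovery_log.json", "w") as fh:
        json.dump(
            {
                "selected_k": trace.selected_k,
                "panel": model.mirna_ids,
                "reference_level": norm_spec.reference_level,
                "control_mirna_ids": list(norm_spec.control_mirna_ids),
            },
            fh,
            indent=2,
        )
    return model, trace


def trace_to_frame(trace: GreedySearchTrace) -> pd.DataFrame:
    """Combinations table, one row per panel size (sens/spec/accuracy with
    CIs, in-sample AUC with CI, nested p-values)."""
    rows = []
    for r in trace.rows:
        rows.append(
            {
                "n_mirnas": r.k,
                "panel": ";".join(r.mirna_ids),
                "coefficients": ";".join(f"{c:.6g}" for c in r.model.coefficients),
                "intercept": r.model.intercept,
                "sensitivity": r.sensitivity,
                "sensitivity_ci_low": r.sensitivity_ci[0],
                "sensitivity_ci_high": r.sensitivity_ci[1],
                "specificity": r.specificity,
                "specificity_ci_low": r.specificity_ci[0],
                "specificity_ci_high": r.specificity_ci[1],
                "accuracy": r.accuracy,
                "accuracy_ci_low": r.accuracy_ci[0],
                "accuracy_ci_high": r.accuracy_ci[1],
                "auc": r.auc,
                "auc_ci_low": r.auc_ci[0],
                "auc_ci_high": r.auc_ci[1],
                "p_accuracy_vs_prev": r.p_accuracy_vs_prev,
                "p_auc_vs_prev": r.p_auc_vs_prev,
                "selected": r.k == trace.selected_k,
            }
        )
    return pd.DataFrame(rows)


def _subgroup_rates(df: pd.DataFrame, by: str, correct_col: str) -> dict:
    out = {}
    for level, sub in df.groupby(by, sort=True):
        if level == "none":
            continue
        out[str(level)] = (float(sub[correct_col].mean()), int(len(sub)))
    return out


def run_validation(
    model: LinearDiscriminantModel,
    matrix: ExpressionMatrix,
    samples: SampleTable,
    prevalence: float = 0.00742,
    split: str = "validation",
) -> ValidationReport:
    """Apply a frozen model to the ``validation`` split and report ROC/AUC,
    confusion metrics at the model cutoff, subgroup sensitivity/specificity,
    and predictive values at the configured prevalence."""
    if model.normalization is None:
        raise ValueError("model carries no normalization provenance")
    matrix = align(matrix, samples)
    val_samples = samples.split_subset(split)
    if len(val_samples.df) == 0:
        raise ValueError(f"{split} split is empty")
    val = matrix.subset_samples(val_samples.sample_ids)
    missing = [m for m in model.mirna_ids if m not in val.data.index]
    if missing:
        raise KeyError(f"model miRNA(s) absent from validation matrix: {missing}")
    feats = log_transform(normalize_to_controls(val, model.normalization))
    scores = apply_index(model, feats)
    labels = val_samples.labels(feats.sample_ids)

    table = val_samples.df.copy()
    table["index"] = scores.loc[table["sample_id"]].to_numpy()
    table["predicted_case"] = table["index"] >= model.cutoff
    table["correct"] = table["predicted_case"] == (table["group"] == "case")

    roc = auc_with_delong(scores.to_numpy()[labels], scores.to_numpy()[~labels])
    cm = confusion_at_cutoff(scores.to_numpy(), labels, model.cutoff)

    cases = table[table["group"] == "case"]
    controls = table[table["group"] == "control"]
    sens_stage = _subgroup_rates(cases, "stage", "correct")
    sens_hist = _subgroup_rates(cases, "histology", "correct")
    spec_source = _subgroup_rates(controls, "control_source", "correct")
    ppv, npv = predictive_values(cm.sensitivity, cm.specificity, prevalence)
    return ValidationReport(
        roc=roc,
        confusion=cm,
        specificity_by_source=spec_source,
        sensitivity_by_stage=sens_stage,
        sensitivity_by_histology=sens_hist,
        ppv=ppv,
        npv=npv,
        prevalence=prevalence,
        index_table=table,
    )


def _standardize_panel(features: ExpressionMatrix, panel) -> pd.DataFrame:
    """Panel features standardized per miRNA (mean 0, sd 1 across samples);
    zero-variance miRNAs are dropped with a warning. Returns samples x
    features."""
    X = features.data.loc[list(panel)].T  # samples x panel
    sd = X.std(axis=0, ddof=1)
    dead = sd[sd == 0].index.tolist()
    if dead:
        warnings.warn(f"dropping zero-variance miRNA(s) {dead}", stacklevel=3)
        X = X.drop(columns=dead)
        sd = sd.drop(dead)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 varying panel miRNAs")
    return (X - X.mean(axis=0)) / sd


def cluster_summary(
    features: ExpressionMatrix, samples: SampleTable, panel=None
) -> ClusterSummary:
    """Unsupervised hierarchical clustering of samples on the panel
    features: distance = 1 - Pearson correlation between samples, Ward
    linkage, cut at 2 clusters; agreement is the best matching fraction
    against the true case/control labels over cluster relabelings."""
    panel = list(panel) if panel is not None else features.mirna_ids
    X = _standardize_panel(features, panel)
    corr = np.corrcoef(X.to_numpy())
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="ward")
    assign = fcluster(z, t=2, criterion="maxclust")
    order = [X.index[i] for i in leaves_list(z)]
    labels = samples.labels(list(X.index))
    agreement = max(
        float((np.where(assign == 1, a, b) == labels).mean())
        for a, b in permutations([True, False], 2)
    )
    return ClusterSummary(
        leaf_order=order,
        assignments=pd.Series(assign, index=X.index, name="cluster"),
        agreement=agreement,
    )


def pca_summary(features: ExpressionMatrix, panel=None) -> PCASummary:
    """PCA of the standardized panel features (eigendecomposition of the
    feature correlation structure). Explained-variance fractions are over
    all components and sum to 1; sample coordinates are reported for the
    first three components (sign arbitrary per axis)."""
    panel = list(panel) if panel is not None else features.mirna_ids
    X = _standardize_panel(features, panel)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples for PCA")
    A = X.to_numpy()
    cov = A.T @ A / (A.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    fractions = eigval / eigval.sum()
    k = min(3, len(eigval))
    coords = pd.DataFrame(
        A @ eigvec[:, :k],
        index=X.index,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PCASummary(explained_fractions=fractions, coordinates=coords)
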