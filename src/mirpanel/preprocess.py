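"""Internal-control normalization, control-stability assessment, robust
expression filtering, and the log2 feature transform.

Microarray serum profiles carry a per-sample multiplicative technical
factor (input serum volume, labeling efficiency, hybridization). Dividing
every signal of a sample by the mean of three stable internal-control
miRNAs cancels that factor; multiplying by a frozen reference level keeps
values on the familiar raw-signal scale, so the conventional robustness
threshold of 64 fluorescence units stays meaningful. The reference level is
estimated once on discovery data and reused unchanged on validation or new
cohorts, so no information flows backwards.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, NormalizationSpec, SampleTable

__all__ = [
    "FilterSpec",
    "control_stability",
    "estimate_reference_level",
    "fit_normalization",
    "normalize_to_controls",
    "robust_filter",
    "log_transform",
]


@dataclass
class FilterSpec:
    """Robust-expression rule: keep a miRNA iff its normalized signal
    strictly exceeds ``signal_threshold`` in strictly more than
    ``sample_fraction`` of the samples, in each group (default) or in at
    least one group."""

    signal_threshold: float = 64.0
    sample_fraction: float = 0.5
    group_rule: str = "each_group"

    def __post_init__(self) -> None:
        if not self.signal_threshold > 0:
            raise ValueError("signal_threshold must be > 0")
        if not 0 < self.sample_fraction < 1:
            raise ValueError("sample_fraction must lie in (0, 1)")
        if self.group_rule not in ("each_group", "any_group"):
            raise ValueError(f"unknown group_rule {self.group_rule!r}")


def control_stability(
    matrix: ExpressionMatrix, control_ids: Sequence[str]
) -> pd.Series:
    """Pairwise-variation stability M for each candidate control miRNA.

    M_j is the mean, over the other controls k, of the standard deviation
    across samples of log2(x_j / x_k); lower is more stable. A sample-wide
    multiplicative factor cancels inside the ratio, so M measures exactly
    the co-stability that internal-control normalization relies on.
    """
    control_ids = list(control_ids)
    if len(control_ids) < 2:
        raise ValueError("need at least 2 control miRNAs")
    missing = [c for c in control_ids if c not in matrix.data.index]
    if missing:
        raise KeyError(f"control miRNA(s) absent from matrix: {missing}")
    X = matrix.data.loc[control_ids].to_numpy()
    if (X <= 0).any():
        raise ValueError("control miRNA signals must be strictly positive")
    logx = np.log2(X)
    m = np.zeros(len(control_ids))
    for j in range(len(control_ids)):
        sds = [
            np.std(logx[j] - logx[k], ddof=1)
            for k in range(len(control_ids))
            if k != j
        ]
        m[j] = float(np.mean(sds))
    return pd.Series(m, index=control_ids, name="M")


def estimate_reference_level(
    matrix: ExpressionMatrix, control_ids: Sequence[str]
) -> float:
    """Grand mean of per-sample control-miRNA means (the frozen reference)."""
    control_ids = list(control_ids)
    missing = [c for c in control_ids if c not in matrix.data.index]
    if missing:
        raise KeyError(f"control miRNA(s) absent from matrix: {missing}")
    per_sample = matrix.data.loc[control_ids].to_numpy().mean(axis=0)
    return float(per_sample.mean())


def fit_normalization(
    matrix: ExpressionMatrix, control_ids: Sequence[str]
) -> NormalizationSpec:
    """Estimate a NormalizationSpec (reference level) on a discovery matrix."""
    return NormalizationSpec(
        control_mirna_ids=tuple(control_ids),
        reference_level=estimate_reference_level(matrix, control_ids),
    )


def normalize_to_controls(
    matrix: ExpressionMatrix, spec: NormalizationSpec
) -> ExpressionMatrix:
    """Rescale each sample so its mean control signal equals the frozen
    reference level: value <- value * reference / mean(controls in sample).

    Idempotent given the same spec, and invariant to any per-sample
    multiplicative factor.
    """
    if matrix.scale not in ("raw", "normalized"):
        raise ValueError(f"cannot normalize a matrix on scale {matrix.scale!r}")
    ids = list(spec.control_mirna_ids)
    missing = [c for c in ids if c not in matrix.data.index]
    if missing:
        raise KeyError(f"control miRNA(s) absent from matrix: {missing}")
    control_mean = matrix.data.loc[ids].to_numpy().mean(axis=0)
    zero = np.flatnonzero(control_mean <= 0)
    if zero.size:
        raise ValueError(
            f"zero control-miRNA mean in sample(s) "
            f"{[matrix.sample_ids[i] for i in zero[:5]]}"
        )
    factors = spec.reference_level / control_mean
    return ExpressionMatrix(matrix.data * factors, scale="normalized")


def robust_filter(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    spec: FilterSpec = FilterSpec(),
    exclude_ids: Sequence[str] = (),
) -> list[str]:
    """Select robustly expressed miRNAs on a normalized matrix.

    A miRNA is kept iff the fraction of samples with signal strictly above
    the threshold is strictly above ``sample_fraction``, evaluated per group
    and combined per ``group_rule`` (``each_group``: must pass in both the
    case and the control group). Internal-control miRNAs (``exclude_ids``)
    are never candidates. Order follows the matrix row order.
    """
    if matrix.scale != "normalized":
        raise ValueError("robust_filter expects a normalized matrix")
    labels = samples.labels(matrix.sample_ids)
    if labels.all() or not labels.any():
        raise ValueError("both case and control groups must be nonempty")
    X = matrix.values
    above = X > spec.signal_threshold
    frac_case = above[:, labels].mean(axis=1)
    frac_ctl = above[:, ~labels].mean(axis=1)
    pass_case = frac_case > spec.sample_fraction
    pass_ctl = frac_ctl > spec.sample_fraction
    if spec.group_rule == "each_group":
        keep = pass_case & pass_ctl
    else:
        keep = pass_case | pass_ctl
    excluded = set(exclude_ids)
    return [m for m, k in zip(matrix.mirna_ids, keep) if k and m not in excluded]


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2 of normalized signal, floored at 1 (so values map to >= 0)."""
    if matrix.scale != "normalized":
        raise ValueError("log_transform expects a normalized matrix")
    return ExpressionMatrix(
        pd.DataFrame(
            np.log2(np.maximum(matrix.values, 1.0)),
            index=matrix.data.index,
            columns=matrix.data.columns,
        ),
        scale="log2",
    )
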