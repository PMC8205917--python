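"""Data model and on-disk formats for serum miRNA cohorts.

Three artifacts travel between pipeline stages:

* an expression matrix (miRNAs x samples, TSV, optional ``#scale=`` header)
  carrying raw, normalized, or log2 signal intensities;
* a sample metadata table (TSV) with group labels and clinical covariates;
* a linear discriminant model (JSON) — an ordered miRNA panel with one
  weight per member, an intercept, and a classification cutoff, plus the
  normalization provenance its coefficients assume.

The scale tag travels with files so a model fitted on log2 normalized
signal can never silently be applied to raw intensities.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleTable",
    "LinearDiscriminantModel",
    "NormalizationSpec",
    "FormatError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_table",
    "write_sample_table",
    "read_model",
    "write_model",
    "apply_index",
    "align",
]

SCALES = ("raw", "normalized", "log2")
GROUPS = ("case", "control")
CONTROL_SOURCES = ("A", "B", "C", "none")
GENDERS = ("male", "female")
STAGES = ("IA", "IB", "II", "none")
HISTOLOGIES = ("differentiated", "undifferentiated", "special", "none")
SPLITS = ("discovery", "validation", "unassigned")

#: metadata TSV header, in canonical order
SAMPLE_COLUMNS = (
    "sample_id",
    "group",
    "control_source",
    "age",
    "gender",
    "stage",
    "histology",
    "split",
)


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


@dataclass
class ExpressionMatrix:
    """miRNA signal intensities, miRNAs x samples.

    ``data`` is a DataFrame indexed by miRNA id with one column per sample.
    ``scale`` is one of ``raw``, ``normalized`` or ``log2`` and changes only
    through the declared preprocessing operations.
    """

    data: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale tag {self.scale!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate miRNA id {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            raise ValueError("expression values must be finite")
        if self.scale in ("raw", "normalized") and (values < 0).any():
            raise ValueError(f"{self.scale} signal values must be >= 0")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data[list(sample_ids)], self.scale)

    def subset_mirnas(self, mirna_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [m for m in mirna_ids if m not in self.data.index]
        if missing:
            raise KeyError(f"miRNAs not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(mirna_ids)], self.scale)


@dataclass
class SampleTable:
    """Per-sample group labels and clinical covariates.

    Cases carry a pathological stage and histology and no control source;
    controls carry a control source (serum bank A/B/C) and no stage or
    histology. The ``split`` column records discovery/validation membership.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"sample table missing columns {missing}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample id {dup!r}")
        for col, allowed in (
            ("group", GROUPS),
            ("control_source", CONTROL_SOURCES),
            ("gender", GENDERS),
            ("stage", STAGES),
            ("histology", HISTOLOGIES),
            ("split", SPLITS),
        ):
            bad = set(df[col].unique()) - set(allowed)
            if bad:
                raise FormatError(
                    f"invalid {col} value(s) {sorted(bad)}; allowed: {allowed}"
                )
        cases = df["group"] == "case"
        if (df.loc[cases, "control_source"] != "none").any():
            bad = df.loc[cases & (df["control_source"] != "none"), "sample_id"].iloc[0]
            raise FormatError(f"case {bad!r} has a control_source set")
        controls = ~cases
        for col in ("stage", "histology"):
            if (df.loc[controls, col] != "none").any():
                bad = df.loc[controls & (df[col] != "none"), "sample_id"].iloc[0]
                raise FormatError(f"control {bad!r} has {col} set")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    def subset(self, mask) -> "SampleTable":
        return SampleTable(self.df.loc[mask].reset_index(drop=True))

    def split_subset(self, split: str) -> "SampleTable":
        return self.subset(self.df["split"] == split)

    def labels(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        """Boolean case indicator, optionally in a given sample order."""
        s = self.df.set_index("sample_id")["group"]
        if sample_ids is not None:
            s = s.loc[list(sample_ids)]
        return (s == "case").to_numpy()


@dataclass
class NormalizationSpec:
    """Frozen internal-control normalization: 3 stable control miRNAs and
    the reference level (grand mean of per-sample control means, estimated
    on discovery data and reused unchanged on later cohorts)."""

    control_mirna_ids: tuple[str, str, str]
    reference_level: float

    def __post_init__(self) -> None:
        self.control_mirna_ids = tuple(self.control_mirna_ids)
        if len(self.control_mirna_ids) != 3:
            raise ValueError("exactly 3 control miRNAs are required")
        if not self.reference_level > 0:
            raise ValueError("reference_level must be > 0")


@dataclass
class LinearDiscriminantModel:
    """A fitted diagnostic index: score = sum(coef_k * feature_k) + intercept,
    classified as case iff score >= cutoff (ties count as positive — the
    screening setting favors sensitivity)."""

    mirna_ids: list[str]
    coefficients: np.ndarray
    intercept: float
    cutoff: float = 0.0
    feature_scale: str = "log2"
    normalization: NormalizationSpec | None = None

    def __post_init__(self) -> None:
        self.mirna_ids = list(self.mirna_ids)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.mirna_ids) < 1:
            raise ValueError("panel must contain at least one miRNA")
        if len(self.mirna_ids) != len(self.coefficients):
            raise ValueError(
                f"{len(self.mirna_ids)} miRNA ids but "
                f"{len(self.coefficients)} coefficients"
            )
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValueError("duplicate miRNA ids in panel")
        if self.feature_scale not in SCALES:
            raise ValueError(f"unknown feature_scale {self.feature_scale!r}")

    def with_intercept(self, intercept: float) -> "LinearDiscriminantModel":
        return replace(self, intercept=float(intercept))


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a miRNAs-x-samples TSV.

    First column holds miRNA ids, the header row holds sample ids. An
    optional first line ``#scale=raw|normalized|log2`` declares the scale
    (default raw).
    """
    path = Path(path)
    scale = "raw"
    skip = 0
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#scale="):
        scale = first[len("#scale="):].strip()
        if scale not in SCALES:
            raise FormatError(f"unknown scale tag {scale!r} in {path}")
        skip = 1
    df = pd.read_csv(path, sep="\t", skiprows=skip, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.index.name = "mirna_id"
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate miRNA id {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"duplicate sample id {dup!r} in {path}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric value {df.iat[r, c]!r} at miRNA {df.index[r]!r}, "
            f"sample {df.columns[c]!r} in {path}"
        )
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(
            f"missing value at miRNA {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    # python float() is correctly rounded; pandas' fast parser is not
    exact = df.map(float)
    return ExpressionMatrix(exact, scale)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the TSV form; floats use shortest round-trip repr so that
    read(write(m)) reproduces values bit-exactly."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#scale={matrix.scale}\n")
        fh.write("mirna_id\t" + "\t".join(map(str, matrix.sample_ids)) + "\n")
        for mid, row in zip(matrix.mirna_ids, matrix.values):
            fh.write(str(mid) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_sample_table(path: str | Path) -> SampleTable:
    """Read the metadata TSV. A case with a missing stage or histology is
    filled as ``none`` with a warning; other enum violations are errors."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"sample table {path} missing columns {missing}")
    for col in ("stage", "histology"):
        hole = df[col].isna() & (df["group"] == "case")
        if hole.any():
            warnings.warn(
                f"{int(hole.sum())} case sample(s) missing {col}; filled as 'none'",
                stacklevel=2,
            )
    for col in ("control_source", "stage", "histology", "split"):
        df[col] = df[col].fillna("none" if col != "split" else "unassigned")
    df["age"] = pd.to_numeric(df["age"], errors="raise")
    return SampleTable(df[list(SAMPLE_COLUMNS)].copy())


def write_sample_table(samples: SampleTable, path: str | Path) -> None:
    samples.df.to_csv(path, sep="\t", index=False)


def align(matrix: ExpressionMatrix, samples: SampleTable) -> ExpressionMatrix:
    """Check that matrix and metadata describe the same samples; return the
    matrix with columns reordered to the metadata order.

    Raises with the symmetric difference of the two id sets on mismatch.
    """
    mat_ids = set(matrix.sample_ids)
    meta_ids = set(samples.sample_ids)
    if mat_ids != meta_ids:
        only_mat = sorted(mat_ids - meta_ids)
        only_meta = sorted(meta_ids - mat_ids)
        raise FormatError(
            f"sample id mismatch: matrix-only {only_mat[:10]}, "
            f"metadata-only {only_meta[:10]}"
        )
    return matrix.subset_samples(samples.sample_ids)


def write_model(model: LinearDiscriminantModel, path: str | Path) -> None:
    payload: dict = {
        "mirna_ids": model.mirna_ids,
        "coefficients": [float(c) for c in model.coefficients],
        "intercept": float(model.intercept),
        "cutoff": float(model.cutoff),
        "feature_scale": model.feature_scale,
    }
    if model.normalization is not None:
        payload["normalization"] = {
            "control_mirna_ids": list(model.normalization.control_mirna_ids),
            "reference_level": float(model.normalization.reference_level),
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_model(path: str | Path) -> LinearDiscriminantModel:
    with open(path) as fh:
        payload = json.load(fh)
    required = ("mirna_ids", "coefficients", "intercept", "cutoff", "feature_scale")
    missing = [k for k in required if k not in payload]
    if missing:
        raise FormatError(f"model file {path} missing keys {missing}")
    norm = None
    if payload.get("normalization") is not None:
        norm = NormalizationSpec(
            control_mirna_ids=tuple(payload["normalization"]["control_mirna_ids"]),
            reference_level=float(payload["normalization"]["reference_level"]),
        )
    try:
        return LinearDiscriminantModel(
            mirna_ids=payload["mirna_ids"],
            coefficients=np.asarray(payload["coefficients"], dtype=float),
            intercept=float(payload["intercept"]),
            cutoff=float(payload["cutoff"]),
            feature_scale=payload["feature_scale"],
            normalization=norm,
        )
    except ValueError as exc:
        raise FormatError(f"invalid model file {path}: {exc}") from exc


def apply_index(model: LinearDiscriminantModel, features: ExpressionMatrix) -> pd.Series:
    """Evaluate the diagnostic index on every sample of ``features``.

    ``features`` must carry the scale the model's coefficients assume
    (``model.feature_scale``); a mismatch is an error, not a warning,
    because index values on the wrong scale are silently meaningless.
    """
    if features.scale != model.feature_scale:
        raise ValueError(
            f"feature scale {features.scale!r} does not match model scale "
            f"{model.feature_scale!r}"
        )
    missing = [m for m in model.mirna_ids if m not in features.data.index]
    if missing:
        raise KeyError(f"model miRNA(s) absent from features: {missing}")
    X = features.data.loc[model.mirna_ids].to_numpy()  # panel x samples
    scores = model.coefficients @ X + model.intercept
    return pd.Series(scores, index=features.sample_ids, name="index")
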