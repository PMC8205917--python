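import numpy as np
import pandas as pd
import pytest

from mirpanel import (
    ExpressionMatrix,
    LinearDiscriminantModel,
    SampleTable,
    SimulationConfig,
    generate_cohort,
    split_discovery_validation,
)


@pytest.fixture
def egc_model() -> LinearDiscriminantModel:
    """The published four-miRNA early-gastric-cancer index."""
    return LinearDiscriminantModel(
        mirna_ids=["miR-4257", "miR-6785-5p", "miR-187-5p", "miR-5739"],
        coefficients=[2.06054, -1.25451, 0.834875, -1.07189],
        intercept=-4.4385,
        cutoff=0.0,
        feature_scale="log2",
    )


@pytest.fixture
def single_mirna_model() -> LinearDiscriminantModel:
    """The published best single-miRNA discriminant."""
    return LinearDiscriminantModel(
        mirna_ids=["miR-6511b-5p"],
        coefficients=[0.952637],
        intercept=-5.80077,
        cutoff=0.0,
        feature_scale="log2",
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort with splits assigned (seed 7)."""
    cfg = SimulationConfig(seed=7)
    matrix, samples = generate_cohort(cfg)
    samples = split_discovery_validation(samples, ratio=0.5, seed=7)
    return cfg, matrix, samples


def random_matrix(rng: np.random.Generator, n_mirna=20, n_sample=8,
                  scale="raw") -> ExpressionMatrix:
    values = rng.uniform(1.0, 1000.0, size=(n_mirna, n_sample))
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=pd.Index([f"miR-t-{i}" for i in range(n_mirna)], name="mirna_id"),
            columns=[f"S{j}" for j in range(n_sample)],
        ),
        scale=scale,
    )


def feature_matrix(X: np.ndarray, ids=None, scale="log2") -> ExpressionMatrix:
    """samples-x-features array -> ExpressionMatrix (features x samples)."""
    X = np.asarray(X, float)
    ids = ids or [f"f{j}" for j in range(X.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(X.T, index=pd.Index(ids, name="mirna_id"),
                     columns=[f"S{i}" for i in range(X.shape[0])]),
        scale=scale,
    )


def simple_samples(labels, ids=None) -> SampleTable:
    labels = np.asarray(labels, bool)
    ids = ids or [f"S{i}" for i in range(len(labels))]
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": ids,
                "group": np.where(labels, "case", "control"),
                "control_source": np.where(labels, "none", "A"),
                "age": 65.0,
                "gender": "male",
                "stage": np.where(labels, "IA", "none"),
                "histology": np.where(labels, "differentiated", "none"),
                "split": "unassigned",
            }
        )
    )
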