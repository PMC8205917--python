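"""Unsupervised structure of the selected panel on the validation arm:
hierarchical clustering (Pearson dissimilarity, Ward linkage) and PCA of
the standardized panel features.

Writes results/unsupervised/cluster_assignments.tsv and pca.tsv.
"""

from pathlib import Path

import pandas as pd

from mirpanel import (
    cluster_summary,
    log_transform,
    normalize_to_controls,
    pca_summary,
    read_expression_matrix,
    read_model,
    read_sample_table,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    model = read_model(ROOT / "discovery" / "model.json")
    matrix = read_expression_matrix(ROOT / "cohort" / "matrix.tsv")
    samples = read_sample_table(ROOT / "cohort" / "metadata.tsv")
    val_s = samples.split_subset("validation")
    val = matrix.subset_samples(val_s.sample_ids)
    feats = log_transform(normalize_to_controls(val, model.normalization))

    clusters = cluster_summary(feats, val_s, panel=model.mirna_ids)
    print(
        f"2-cluster cut (Ward on 1 - Pearson r, {len(model.mirna_ids)} panel "
        f"miRNAs): agreement with case/control labels "
        f"{clusters.agreement:.3f}"
    )

    pca = pca_summary(feats, panel=model.mirna_ids)
    frac3 = pca.explained_fractions[:3].sum()
    print(
        "PCA explained-variance fractions: "
        + ", ".join(f"{f:.1%}" for f in pca.explained_fractions)
        + f" (first three: {frac3:.1%})"
    )

    out = ROOT / "unsupervised"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "sample_id": clusters.assignments.index,
            "cluster": clusters.assignments.to_numpy(),
            "group": val_s.df.set_index("sample_id")
            .loc[clusters.assignments.index, "group"]
            .to_numpy(),
        }
    ).to_csv(out / "cluster_assignments.tsv", sep="\t", index=False)
    coords = pca.coordinates.copy()
    coords.insert(0, "sample_id", coords.index)
    coords.to_csv(out / "pca.tsv", sep="\t", index=False)
    print(f"wrote {out}/cluster_assignments.tsv and pca.tsv")


if __name__ == "__main__":
    main()
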