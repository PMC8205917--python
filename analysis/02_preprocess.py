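"""Assess internal-control stability, normalize the discovery arm, and
apply the robust-expression filter.

Reports the geNorm-style stability M of each internal control (lower is
more stable; M > 1 would make normalization suspect), the frozen reference
level, and the number of miRNAs whose normalized signal exceeds 64 units
in more than half the samples of each group.

Writes results/preprocess_summary.tsv and results/candidates.txt.
"""

from pathlib import Path

import pandas as pd

from mirpanel import (
    FilterSpec,
    control_stability,
    fit_normalization,
    normalize_to_controls,
    read_expression_matrix,
    read_sample_table,
    robust_filter,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
CONTROLS = ("miR-ctl-1", "miR-ctl-2", "miR-ctl-3")


def main() -> None:
    matrix = read_expression_matrix(ROOT / "cohort" / "matrix.tsv")
    samples = read_sample_table(ROOT / "cohort" / "metadata.tsv")
    disc_s = samples.split_subset("discovery")
    disc = matrix.subset_samples(disc_s.sample_ids)

    stability = control_stability(disc, CONTROLS)
    print("internal-control stability M (log2-ratio sd, lower = stabler):")
    for mid, m in stability.items():
        print(f"  {mid}: {m:.4f}")

    spec = fit_normalization(disc, CONTROLS)
    print(f"frozen reference level: {spec.reference_level:.1f} signal units")

    normalized = normalize_to_controls(disc, spec)
    kept = robust_filter(normalized, disc_s, FilterSpec(), exclude_ids=CONTROLS)
    print(
        f"robust filter: {len(kept)} of {disc.shape[0]} miRNAs exceed 64 "
        "normalized units in >50% of samples of each group"
    )

    pd.DataFrame(
        {
            "control_mirna": stability.index,
            "stability_M": stability.to_numpy(),
            "reference_level": spec.reference_level,
            "n_candidates": len(kept),
        }
    ).to_csv(ROOT / "preprocess_summary.tsv", sep="\t", index=False)
    (ROOT / "candidates.txt").write_text("\n".join(kept) + "\n")
    print(f"wrote {ROOT}/preprocess_summary.tsv and candidates.txt")


if __name__ == "__main__":
    main()
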