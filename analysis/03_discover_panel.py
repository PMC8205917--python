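"""Greedy Fisher-LDA panel discovery on the discovery arm.

Grows panels forward by LOOCV accuracy up to five miRNAs, compares
consecutive sizes with the paired DeLong test, selects the panel size, and
recentres the final index so the Youden-optimal cutoff sits at zero.

Writes results/discovery/model.json, combinations.tsv, discovery_log.json.
"""

from pathlib import Path

import pandas as pd

from mirpanel import RunConfig, run_discovery

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = RunConfig(
        matrix_path=str(ROOT / "cohort" / "matrix.tsv"),
        metadata_path=str(ROOT / "cohort" / "metadata.tsv"),
        out_dir=str(ROOT / "discovery"),
    )
    model, trace = run_discovery(cfg)
    table = pd.read_csv(ROOT / "discovery" / "combinations.tsv", sep="\t")
    cols = ["n_mirnas", "panel", "accuracy", "auc", "p_auc_vs_prev", "selected"]
    print("best combination per panel size (discovery arm, LOOCV):")
    print(table[cols].to_string(index=False))
    print(
        f"\nselected {trace.selected_k}-miRNA index: "
        + " + ".join(
            f"({c:.5g}) x {m}"
            for c, m in zip(model.coefficients, model.mirna_ids)
        )
        + f" + ({model.intercept:.5g}), cutoff 0"
    )


if __name__ == "__main__":
    main()
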