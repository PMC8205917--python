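"""Generate the synthetic case-control serum miRNA cohort used by the rest
of the analysis and split it 1:1 into discovery and validation arms.

The cohort mimics a matched case-control serum microarray study: 200
early-cancer cases and 200 controls (three serum sources), 300 miRNAs with
log-normal signals and a detection floor, three stable internal-control
miRNAs, a per-sample technical factor, and four planted markers — one of
them a suppressor whose marginal discrimination is at chance.

Writes results/cohort/matrix.tsv and results/cohort/metadata.tsv.
"""

from pathlib import Path

from mirpanel import (
    SimulationConfig,
    generate_cohort,
    split_discovery_validation,
    write_expression_matrix,
    write_sample_table,
)

SEED = 20260926
OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    matrix, samples = generate_cohort(cfg)
    samples = split_discovery_validation(samples, ratio=0.5, seed=SEED)
    OUT.mkdir(parents=True, exist_ok=True)
    write_expression_matrix(matrix, OUT / "matrix.tsv")
    write_sample_table(samples, OUT / "metadata.tsv")
    df = samples.df
    print(f"cohort: {matrix.shape[0]} miRNAs x {matrix.shape[1]} samples")
    for split in ("discovery", "validation"):
        sub = df[df["split"] == split]
        print(
            f"  {split}: {(sub['group'] == 'case').sum()} cases / "
            f"{(sub['group'] == 'control').sum()} controls"
        )
    print(f"planted markers: {[m.mirna_id for m in cfg.planted_markers]}")
    print(f"wrote {OUT}/matrix.tsv and metadata.tsv")


if __name__ == "__main__":
    main()
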