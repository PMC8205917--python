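"""Validate the frozen diagnostic index on the held-out validation arm.

Applies the saved normalization reference and model to validation samples
only, then reports ROC/AUC with DeLong CI, sensitivity/specificity/accuracy
at the cutoff, per-control-source specificity, per-stage and per-histology
sensitivity, and PPV/NPV at a screening prevalence of 0.742%.

Writes results/validation/validation.json and index_table.tsv.
"""

import json
from pathlib import Path

from mirpanel import (
    read_expression_matrix,
    read_model,
    read_sample_table,
    run_validation,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    model = read_model(ROOT / "discovery" / "model.json")
    matrix = read_expression_matrix(ROOT / "cohort" / "matrix.tsv")
    samples = read_sample_table(ROOT / "cohort" / "metadata.tsv")
    report = run_validation(model, matrix, samples, prevalence=0.00742)

    out = ROOT / "validation"
    out.mkdir(parents=True, exist_ok=True)
    report.index_table.to_csv(out / "index_table.tsv", sep="\t", index=False)
    cm = report.confusion
    summary = {
        "auc": report.roc.auc,
        "auc_ci": list(report.roc.auc_ci),
        "sensitivity": cm.sensitivity,
        "sensitivity_ci": list(cm.sensitivity_ci),
        "specificity": cm.specificity,
        "specificity_ci": list(cm.specificity_ci),
        "accuracy": cm.accuracy,
        "accuracy_ci": list(cm.accuracy_ci),
        "specificity_by_source": report.specificity_by_source,
        "sensitivity_by_stage": report.sensitivity_by_stage,
        "sensitivity_by_histology": report.sensitivity_by_histology,
        "ppv": report.ppv,
        "npv": report.npv,
        "prevalence": report.prevalence,
    }
    with open(out / "validation.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    print(f"validation AUC {report.roc.auc:.3f} "
          f"(95% CI {report.roc.auc_ci[0]:.3f}-{report.roc.auc_ci[1]:.3f})")
    print(f"sensitivity {cm.sensitivity:.3f}, specificity {cm.specificity:.3f}, "
          f"accuracy {cm.accuracy:.3f} at cutoff 0")
    print("specificity by control source:",
          {k: f"{v:.3f} (n={n})" for k, (v, n) in
           report.specificity_by_source.items()})
    print("sensitivity by stage:",
          {k: f"{v:.3f} (n={n})" for k, (v, n) in
           report.sensitivity_by_stage.items()})
    print(f"at prevalence {report.prevalence:.5f}: "
          f"PPV {report.ppv:.3f}, NPV {report.npv:.5f}")


if __name__ == "__main__":
    main()
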