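#!/usr/bin/env python
"""Cross-validated risk classification over the sway-feature table.

Runs the full classifier battery under stratified 10-fold CV (pooled
confusion matrices, No-Risk positive), then re-runs the headline gradient
boosting model with backward feature elimination.  Writes the metric table
and the GB confusion matrix to results/.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from swaylift.ml_harness import (
    CLASSIFIER_SPECS,
    CVConfig,
    report_table,
    run_cv_experiment,
)
from swaylift.sway_features import read_feature_table

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

BATTERY = ["SVM", "DT", "GB", "RaF", "XGB", "RoF", "kNN", "MLP", "PNN"]
CV = CVConfig(k=10, seed=0)


def main() -> None:
    table = read_feature_table(RESULTS / "features.csv")

    reports = []
    for name in BATTERY:
        report = run_cv_experiment(table, CLASSIFIER_SPECS[name], CV)
        reports.append(report)
        print(f"{name:4s} accuracy {report.metrics['accuracy']:.3f} "
              f"aucroc {report.metrics['aucroc']:.3f}")

    metrics = report_table(reports)
    metrics.to_csv(RESULTS / "cv_metrics.csv")
    print("\n" + metrics.to_string())

    best = max(reports, key=lambda r: r.metrics["accuracy"])
    print(f"\nbest classifier: {best.classifier}")

    gb_bfe = run_cv_experiment(table, CLASSIFIER_SPECS["GB"], CV, use_bfe=True)
    print(f"\nGB with backward feature elimination: "
          f"accuracy {gb_bfe.metrics['accuracy']:.3f} using "
          f"{len(gb_bfe.selected_features)} features: "
          f"{', '.join(gb_bfe.selected_features)}")
    gb_bfe.confusion.to_frame().to_csv(RESULTS / "gb_confusion.csv")
    pd.DataFrame([dataclasses.asdict(gb_bfe.confusion)]).to_csv(
        RESULTS / "gb_confusion_counts.csv", index=False
    )
    print(gb_bfe.confusion.to_frame().to_string())


if __name__ == "__main__":
    main()
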