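#!/usr/bin/env python
"""Compute the 14 sway statistics for every detected lift window.

Each ROI's z/y windows (cut from the 1-50 Hz filtered signals) are
resampled to 20 Hz, low-passed at 5 Hz and de-meaned; the per-window
feature vectors form the classification table written to results/.
"""

from pathlib import Path

import pandas as pd

from swaylift.segmentation import read_recording_csv, read_rois_csv
from swaylift.sway_features import (
    FEATURE_NAMES,
    feature_table_from_recordings,
    write_feature_table,
)
from swaylift.synthetic import SyntheticRecording

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"


def main() -> None:
    manifest = pd.read_csv(DATA_DIR / "manifest.csv")
    rois = read_rois_csv(RESULTS / "detected_rois.csv")

    recordings = []
    for _, row in manifest.iterrows():
        df, fs = read_recording_csv(DATA_DIR / row["file"])
        recordings.append(SyntheticRecording(
            acc_x=df["acc_x"].to_numpy(),
            acc_y=df["acc_y"].to_numpy(),
            acc_z=df["acc_z"].to_numpy(),
            sampling_rate=fs,
            subject_id=row["subject_id"],
            class_label=row["class_label"],
        ))

    table = feature_table_from_recordings(recordings, rois_by_recording=rois)
    write_feature_table(table, RESULTS / "features.csv")

    print(f"extracted {len(table)} feature vectors "
          f"({table['label'].value_counts().to_dict()})")
    print("\nper-class means of the headline features:")
    print(table.groupby("label")[["MDIST_AP", "MDIST_ML", "MV", "CF"]]
          .mean().round(3).to_string())
    assert list(table.columns[3:]) == FEATURE_NAMES


if __name__ == "__main__":
    main()
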