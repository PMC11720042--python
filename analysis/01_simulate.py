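#!/usr/bin/env python
"""Generate the synthetic lifting dataset the rest of the analysis consumes.

Eight subjects, two sessions each (No-Risk at 2.5 lifts/min, Risk at
6 lifts/min), 20 lifts per session at 128 Hz.  Recording CSVs are large and
go to scratch/data/; the manifest and ground-truth lift windows go to
results/.
"""

from pathlib import Path

from swaylift import SimulationConfig
from swaylift.synthetic import generate_dataset, write_dataset_csv

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"

SEED = 42


def main() -> None:
    config = SimulationConfig(seed=SEED)
    recordings, labels = generate_dataset(config)
    write_dataset_csv(recordings, labels, DATA_DIR)

    RESULTS.mkdir(exist_ok=True)
    for name in ("manifest.csv", "true_rois.csv"):
        (RESULTS / name).write_text((DATA_DIR / name).read_text())

    n_rois = sum(len(r.true_rois) for r in recordings)
    minutes = sum(len(r) for r in recordings) / config.sampling_rate / 60
    print(f"generated {len(recordings)} recordings ({minutes:.0f} min of signal) "
          f"with {n_rois} ground-truth lifts -> {DATA_DIR}")
    print(f"class separation delta = {config.delta:.2f}, seed = {SEED}")


if __name__ == "__main__":
    main()
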