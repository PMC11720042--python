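import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from swaylift import SimulationConfig
from swaylift.sway_features import Stabilogram
from swaylift.synthetic import generate_dataset
from swaylift.sway_features import feature_table_from_recordings


def random_stabilogram(rng: np.random.Generator, n: int | None = None) -> Stabilogram:
    """A smooth random stabilogram (band-limited enough to look like sway)."""
    n = n or int(rng.integers(40, 120))
    ap = np.cumsum(rng.standard_normal(n))
    ml = np.cumsum(rng.standard_normal(n))
    return Stabilogram(ap - ap.mean(), ml - ml.mean(), fs=20.0)


@pytest.fixture(scope="session")
def default_feature_table():
    """Feature table for one default synthetic dataset (ground-truth windows)."""
    recs, _ = generate_dataset(SimulationConfig(seed=11))
    return feature_table_from_recordings(recs)
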