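import numpy as np
import pandas as pd
import pytest

from ran_mvpa import (
    Parcellation,
    SyntheticConfig,
    generate_dataset,
    generate_parcellation,
)

# A scaled-down study design used by structural/unit tests: same nested
# three-visit layout, smaller groups so LOO loops stay fast.
SMALL_CONFIG = SyntheticConfig(
    group_sizes=((12, 12), (9, 9), (6, 6)),
    effect_sizes=(0.0, 0.6, 1.2),
    seed=7,
)


@pytest.fixture(scope="session")
def parcellation() -> Parcellation:
    return generate_parcellation()


@pytest.fixture(scope="session")
def small_dataset():
    """(parcellation, cohort, maps) for a small nested two-group cohort."""
    return generate_dataset(SMALL_CONFIG)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_parcellation() -> Parcellation:
    """A hand-built 4x4x3 parcellation: two homolog pairs and one midline
    region, small enough for exhaustive loop oracles."""
    labels = np.zeros((4, 4, 3), dtype=np.int32)
    labels[0, 0:2, 0] = 1   # left pair A (2 voxels)
    labels[3, 0:2, 0] = 2   # right pair A
    labels[0, 2:4, 1] = 3   # left pair B
    labels[3, 2:4, 1] = 4   # right pair B
    labels[1:3, 1, 2] = 5   # midline
    table = pd.DataFrame(
        {
            "label": [1, 2, 3, 4, 5],
            "name": ["left A", "right A", "left B", "right B", "mid"],
            "hemisphere": ["L", "R", "L", "R", "midline"],
            "homolog_label": pd.array([2, 1, 4, 3, None], dtype="Int64"),
        }
    )
    return Parcellation(labels=labels, table=table)
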