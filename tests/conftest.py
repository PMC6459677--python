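import numpy as np
import pandas as pd
import pytest

from dpanet.expression import normalize_cptt_log, population_profiles
from dpanet.synthetic import SyntheticDesign, generate_dataset


def make_cohort(spec: dict[str, dict[str, int]]) -> pd.DataFrame:
    """Build an annotation frame from {condition: {cluster: n_cells}}."""
    rows = []
    i = 0
    for cond, clusters in spec.items():
        for cluster, n in clusters.items():
            for _ in range(n):
                rows.append((f"c{i:05d}", cond, cluster))
                i += 1
    return pd.DataFrame(rows, columns=["cell_id", "condition", "cluster"])


@pytest.fixture
def toy_cohort() -> pd.DataFrame:
    """20 cells, two conditions, two clusters with a real imbalance."""
    return make_cohort({"A": {"X": 6, "Y": 4}, "B": {"X": 2, "Y": 8}})


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic design at a fixed seed, shared across tests."""
    design = SyntheticDesign(seed=7)
    matrix, annotations, lr_map, truth = generate_dataset(design)
    return design, matrix, annotations, lr_map, truth


@pytest.fixture(scope="session")
def default_profile(default_dataset):
    _, matrix, annotations, _, _ = default_dataset
    return population_profiles(normalize_cptt_log(matrix), annotations)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
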