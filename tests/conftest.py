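import numpy as np
import pandas as pd
import pytest

from immunoscape.cell_tables import CellMap
from immunoscape.synthetic import TumorSimParams, simulate_tumor


def make_cell_map(cancer, lymph, stromal=(), tumour_id="toy", window=None):
    """Small CellMap straight from coordinate lists."""
    rows = (
        [(x, y, "cancer") for x, y in cancer]
        + [(x, y, "lymphocyte") for x, y in lymph]
        + [(x, y, "stromal") for x, y in stromal]
    )
    df = pd.DataFrame(rows, columns=["x", "y", "class"])
    return CellMap(tumour_id, df, window)


@pytest.fixture
def toy_map():
    return make_cell_map(
        cancer=[(0, 0), (10, 0), (0, 10)],
        lymph=[(1, 1), (50, 50)],
        stromal=[(5, 5)],
        window=(0, 0, 100, 100),
    )


#: compact, well-separated tumour used across recovery tests
SMALL_TUMOR = TumorSimParams(
    window=(3000.0, 3000.0),
    nest_rate=1.5,
    offspring_mean=300.0,
    nest_sd=60.0,
    stromal_rate=30.0,
    lymph_counts=(400, 400, 400),
    adjacent_offset=150.0,
    regime_jitter=10.0,
    seed=0,
)


@pytest.fixture(scope="session")
def small_tumor():
    params = SMALL_TUMOR
    cm, labels = simulate_tumor(params)
    return cm, labels, params


def paper_mixture_sample(n, seed=0):
    """Proximity values from the published three-class mixture
    (means 0.011/0.06/0.13, s.d. 0.002/0.0047/0.0045, weights 0.21/0.47/0.32)."""
    rng = np.random.default_rng(seed)
    means = np.array([0.011, 0.06, 0.13])
    sds = np.array([0.002, 0.0047, 0.0045])
    weights = np.array([0.21, 0.47, 0.32])
    comp = rng.choice(3, size=n, p=weights)
    return rng.normal(means[comp], sds[comp]), (means, sds, weights)
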