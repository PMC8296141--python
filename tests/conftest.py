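import numpy as np
import pandas as pd
import pytest

from strigascreen.model import SNPMatrix, StrigaCountSeries
from strigascreen.simulate import TrialSimParams, simulate_trial
from strigascreen.simulate import random_additive_tree  # noqa: F401  (shared helper)


@pytest.fixture
def toy_series() -> StrigaCountSeries:
    return StrigaCountSeries("A1", "field", (35, 49, 63, 70), (0, 2, 6, 4))


@pytest.fixture
def balanced_trial() -> pd.DataFrame:
    """Small balanced lattice trial (8 genotypes, 3 reps, blocks of 4)."""
    params = TrialSimParams(
        n_genotypes=8,
        n_reps=3,
        block_size=4,
        trait_means={"Y": 10.0},
        sigma2_g={"Y": 2.0},
        sigma2_e={"Y": 1.0},
        seed=7,
    )
    return simulate_trial(params)


@pytest.fixture
def biparental_panel() -> SNPMatrix:
    """Two fully informative homozygous parents plus hand-coded progeny.

    Female FEM is 0 and male MAL is 2 at every marker; progeny rows cover
    A/B/H and missing codes.
    """
    calls = np.array(
        [
            [0, 0, 0, 0, 0, 0],
            [2, 2, 2, 2, 2, 2],
            [1, 1, 1, 0, 0, 2],  # 3 het, 2 female-type, 1 male-type
            [0, 0, 0, 0, 0, 0],  # identical to female
            [1, 1, 1, 1, 1, 1],  # F1-like
            [np.nan, 1, 0, 2, np.nan, 0],  # with missing calls
        ],
        dtype=float,
    )
    return SNPMatrix(
        ["FEM", "MAL", "p1", "p2", "p3", "p4"],
        [f"M{i}" for i in range(6)],
        calls,
    )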