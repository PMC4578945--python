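import numpy as np
import pandas as pd
import pytest

from betashift.community import CommunityTable


@pytest.fixture
def toy_table() -> CommunityTable:
    """Three observations, three species — the hand-computed worked example
    with pairwise percentage differences (0.6, 1.0, 0.25)."""
    values = pd.DataFrame(
        [[4.0, 1.0, 0.0], [1.0, 1.0, 3.0], [0.0, 0.0, 3.0]],
        index=["o1", "o2", "o3"],
        columns=["sp1", "sp2", "sp3"],
    )
    meta = pd.DataFrame(
        {"site": ["A", "A", "A"], "time": [1.0, 2.0, 3.0],
         "season": ["wet"] * 3, "replicate": ["t1"] * 3},
        index=values.index,
    )
    return CommunityTable(values, meta)


def random_table(rng: np.random.Generator, n_obs: int = 10, n_species: int = 6,
                 zero_frac: float = 0.3) -> CommunityTable:
    """Random non-negative community table with some structural zeros."""
    vals = rng.gamma(1.5, 2.0, size=(n_obs, n_species))
    vals[rng.random(vals.shape) < zero_frac] = 0.0
    if not vals.any(axis=1).all():  # avoid all-zero observations
        vals[~vals.any(axis=1), 0] = 1.0
    values = pd.DataFrame(
        vals, index=[f"o{i}" for i in range(n_obs)],
        columns=[f"sp{j}" for j in range(n_species)],
    )
    meta = pd.DataFrame(
        {"site": ["S1"] * n_obs, "time": np.arange(n_obs, dtype=float),
         "replicate": ["t1"] * n_obs},
        index=values.index,
    )
    return CommunityTable(values, meta)
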