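import warnings

import numpy as np
import pandas as pd
import pytest

import rankverse as rv


@pytest.fixture(autouse=True)
def _quiet_psis_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Pareto k.*")
        warnings.filterwarnings("ignore", message=".*PSIS tail.*")
        yield


@pytest.fixture(scope="session")
def small_group():
    """10 individuals, one year-block."""
    return rv.simulate_group(rv.GroupConfig(n_individuals=10, n_years=1, seed=7))


@pytest.fixture(scope="session")
def small_events(small_group):
    scale = rv.tune_upset_scale(small_group, 0.007)
    return rv.simulate_supplant_sequence(
        small_group, 200, upset_prob_scale=scale, seed=11
    )


@pytest.fixture(scope="session")
def small_ranks(small_events):
    cfg = rv.MultiverseConfig(elo_k_grid=(0.0,))
    return rv.compute_rank_tables(small_events, cfg)


@pytest.fixture(scope="session")
def latent_ranks(small_group):
    """Rank table built directly from the known latent hierarchy."""
    g = small_group[small_group["year"] == 1]
    return pd.DataFrame(
        {
            "year": 1,
            "id": g["id"].to_numpy(),
            "elo_raw": g["latent_score"].to_numpy(),
            "elo_ordinal": g["ordinal"].to_numpy(),
            "elo_proportional": g["prop_rank"].to_numpy(),
            "davids_raw": g["latent_score"].to_numpy(),
            "davids_ordinal": g["ordinal"].to_numpy(),
            "davids_proportional": g["prop_rank"].to_numpy(),
        }
    )


def z_transform_for(group, year=1):
    """Mean/sd of proportional rank over the complete directed dyad table."""
    g = group[group["year"] == year]
    prop = g["prop_rank"].to_numpy()
    n = len(prop)
    rows = np.repeat(prop, n - 1)  # each id appears n-1 times as sender
    return float(rows.mean()), float(rows.std())
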