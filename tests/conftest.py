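import numpy as np
import pandas as pd
import pytest

import envgxe as ex


@pytest.fixture(scope="session")
def default_sites():
    return ex.simulate_programs(10, seed=0)


@pytest.fixture(scope="session")
def small_panel(default_sites):
    """200 clones x 400 markers with one planted minTemp cline QTL."""
    dm, truth, prog = ex.simulate_genotypes(
        200, 400, default_sites, [ex.EnvQtl(25, "minTemp", 0.15)], seed=7)
    return dm, truth, prog


@pytest.fixture(scope="session")
def balanced_yields(default_sites):
    """Balanced 120-clone x 2x3 trial x 2-rep yield set with g and gYL variance."""
    dm, truth, prog = ex.simulate_genotypes(120, 30, default_sites, seed=3)
    truth.variance_components = {"g": 1.0, "gY": 0.0, "gL": 0.0, "gYL": 0.8, "e": 1.5}
    truth.year_effects = {2020: 2.0, 2021: -1.0, 2022: 0.0}
    truth.loc_effects = {"A": 5.0, "B": -3.0}
    layout = ex.make_trial_layout(dm.clones, ["A", "B"], [2020, 2021, 2022], 2)
    records = ex.simulate_yields(dm, truth, layout, seed=11)
    return records, truth


def polygenic_response(K: pd.DataFrame, h2: float, seed: int) -> pd.Series:
    """Heritable response on a kinship matrix with no single-marker QTL."""
    rng = np.random.default_rng(seed)
    s, U = np.linalg.eigh(K.to_numpy())
    g = U @ (np.sqrt(np.maximum(s, 0.0)) * rng.normal(0, 1, len(s)))
    g = g / g.std() * np.sqrt(h2)
    eps = rng.normal(0, np.sqrt(1 - h2), len(s))
    return pd.Series(g + eps, index=K.index)
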