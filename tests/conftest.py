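import numpy as np
import pandas as pd
import pytest

from stressgwas import synthio
from stressgwas.growthio import PARAM_FIELDS


@pytest.fixture(scope="session")
def strains36():
    return synthio.gen_strains(36, seed=1)


@pytest.fixture(scope="session")
def small_strains():
    return synthio.gen_strains(6, seed=3)


@pytest.fixture(scope="session")
def noise_free_curves(small_strains):
    frame, truth = synthio.gen_growth_curves(
        small_strains, n_conditions=2, levels_per_condition=5,
        n_replicates=1, noise_sd=0.0, seed=7,
    )
    return frame, truth


def make_param_table(values: dict, conditions=("C1",), grew=None) -> pd.DataFrame:
    """Build a growth-parameter table from {strain: {level: 5-vector}}.

    ``values[strain][level]`` is a dict of parameter overrides; unspecified
    parameters default to a common constant so they are uninformative.
    """
    defaults = {"lag_h": 4.0, "mu_max": 0.4, "amplitude": 1.0,
                "t_half": 15.0, "auc": 40.0}
    rows = []
    for cond in conditions:
        for strain, levels in values.items():
            for level, overrides in levels.items():
                row = {"strain": strain, "condition": cond, "level": level,
                       **defaults, **overrides}
                row["grew"] = overrides.get("grew", True) if grew is None else grew
                rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
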