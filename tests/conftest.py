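import numpy as np
import pandas as pd
import pytest

from monoculture.bpmm import ChainConfig
from monoculture.simulate import SyntheticTruth, simulate_effect_table


@pytest.fixture(scope="session")
def smoke_cfg() -> ChainConfig:
    """Short two-chain schedule for pipeline checks (1000 draws/chain)."""
    return ChainConfig(11_000, 1_000, 10, 2)


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic effect-size table with known truth."""
    truth = SyntheticTruth(
        n_species=12, n_studies=16, n_effects=48, n_lncvr=24
    )
    records, corr, info = simulate_effect_table(truth, seed=20260927)
    return records, corr, info


@pytest.fixture()
def balanced_taxonomy() -> pd.DataFrame:
    """Four species in two genera -> balanced ((A,B),(C,D)) topology."""
    return pd.DataFrame(
        {
            "class": ["c1"] * 4,
            "genus": ["g1", "g1", "g2", "g2"],
            "species": list("ABCD"),
        }
    )
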