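import numpy as np
import pandas as pd
import pytest

import crosstaxa as ct


@pytest.fixture(scope="session")
def small_scenario() -> ct.GradientScenario:
    return ct.GradientScenario(
        n_plots=60, n_bact=80, n_fungi=80, n_plant=40, seed=7
    )


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    return ct.generate_dataset(small_scenario)


@pytest.fixture()
def toy_community() -> ct.CommunityTable:
    df = pd.DataFrame(
        [[5.0, 0.0, 2.0], [1.0, 3.0, 0.0], [0.0, 4.0, 4.0], [2.0, 2.0, 2.0]],
        index=[1, 2, 3, 4],
        columns=["spA", "spB", "spC"],
    )
    return ct.CommunityTable(df)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
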