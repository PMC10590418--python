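import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from settlenet.io import CountTable, SampleMetadata
from settlenet.synthetic_data import SimConfig, generate_experiment

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def experiment():
    """One default synthetic experiment shared across tests (seed 11)."""
    return generate_experiment(SimConfig(seed=11))


@pytest.fixture()
def small_table():
    df = pd.DataFrame({"s1": [5, 0, 3], "s2": [1, 2, 0], "s3": [0, 4, 7]},
                      index=["a", "b", "c"])
    return CountTable(df)


@pytest.fixture()
def compartment_setup():
    """Two tetrapods, three compartments each."""
    cols = {f"t{i}_{c}": np.arange(1, 5) * (i + 1) + k
            for i in range(2) for k, c in enumerate(["surface", "crevice", "bottom"])}
    table = CountTable(pd.DataFrame(cols, index=[f"asv{j}" for j in range(4)]))
    meta = SampleMetadata(pd.DataFrame(
        [{"sample_id": f"t{i}_{c}", "conditioning": "aquarium", "time_months": 1,
          "tank_id": "tank0", "tetrapod_id": f"t{i}", "compartment": c}
         for i in range(2) for c in ["surface", "crevice", "bottom"]]))
    return table, meta
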