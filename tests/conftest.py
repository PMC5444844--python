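import pandas as pd
import pytest

from pescreen.synthetic import default_config, generate


@pytest.fixture(scope="session")
def small_registry() -> pd.DataFrame:
    """Registry-calibrated synthetic registry, 20k pregnancies per stratum."""
    return generate(default_config(n_per_stratum=20_000, seed=20240501))


@pytest.fixture(scope="session")
def multiparous(small_registry) -> pd.DataFrame:
    return small_registry[small_registry["parity"] == "multiparous"].reset_index(drop=True)


@pytest.fixture(scope="session")
def primiparous(small_registry) -> pd.DataFrame:
    return small_registry[small_registry["parity"] == "primiparous"].reset_index(drop=True)
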