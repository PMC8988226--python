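import numpy as np
import pandas as pd
import pytest

from mibinet import CountTable


@pytest.fixture
def small_table():
    return CountTable(
        ["s1", "s2", "s3"],
        ["A", "B", "C"],
        np.array([[10, 5, 0], [0, 8, 2], [3, 3, 4]]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def metadata_with_conc():
    conc = [1.0, 2.0, 4.0, 8.0, 16.0, 32.0] * 4
    return pd.DataFrame(
        {"dna_concentration": conc}, index=[f"S{i}" for i in range(24)]
    )
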