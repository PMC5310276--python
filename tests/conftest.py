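import numpy as np
import pytest

from otutopics import OtuTable


@pytest.fixture
def small_table() -> OtuTable:
    counts = np.array([
        [5, 0, 2, 1, 0],
        [3, 4, 0, 2, 1],
        [0, 6, 1, 0, 2],
        [2, 1, 3, 4, 0],
    ])
    labels = {"s1": "control", "s2": "control", "s3": "case", "s4": "case"}
    return OtuTable([f"s{i}" for i in range(1, 5)],
                    [f"g{j}" for j in range(1, 6)], counts, labels)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
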