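import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repo", database=None, derandomize=True)
settings.load_profile("repo")


@pytest.fixture
def rng():
    return np.random.default_rng(20240628)


@pytest.fixture
def k10_frame():
    """Three K10 respondents: all-1s, all-5s, and a mixed row totalling 27."""
    rows = [
        [1] * 10,
        [5] * 10,
        # anxiety items (positions 2,3,5,6) = 2,3,2,3 -> 10;
        # depression items = 3,3,3,3,3,2 -> 17; total 27
        [3, 2, 3, 3, 2, 3, 3, 3, 3, 2],
    ]
    return pd.DataFrame(rows, columns=[f"K10_{i}" for i in range(1, 11)])


def likert_frame(values, prefix, k):
    values = np.asarray(values)
    return pd.DataFrame(values, columns=[f"{prefix}_{i}"
                                         for i in range(1, k + 1)])


@pytest.fixture
def toy_weights():
    """4-node, 2-community signed weighted graph used by path oracles."""
    labels = ["A", "B", "C", "D"]
    w = np.zeros((4, 4))

    def setw(i, j, v):
        w[i, j] = w[j, i] = v

    setw(0, 1, 0.5)    # A-B within community 1
    setw(1, 2, 0.4)    # B-C cross
    setw(2, 3, -0.3)   # C-D within community 2
    setw(0, 2, 0.2)    # A-C cross
    communities = {"A": "c1", "B": "c1", "C": "c2", "D": "c2"}
    return pd.DataFrame(w, index=labels, columns=labels), communities
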