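import numpy as np
import pandas as pd
import pytest

import glycosar as g


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_library():
    p260 = [f"A{i}" for i in range(7)]
    p263 = [f"B{i}" for i in range(7)]
    return p260, p263, g.enumerate_library(p260, p263)


@pytest.fixture
def indicator_49(small_library):
    p260, p263, peps = small_library
    return g.encode_indicators(peps, p260, p263)


@pytest.fixture
def panel():
    return g.load_response_panel()


@pytest.fixture
def reference_pose():
    return g.reference_pose(8)


@pytest.fixture
def toy_score_table(rng):
    peps = g.enumerate_library(["A", "B", "C"], ["X", "Y"])
    table = pd.DataFrame(
        rng.normal(size=(len(peps), 3)),
        index=[p.id for p in peps],
        columns=["f1", "f2", "f3"],
    )
    pep_map = {p.id: (p.p260, p.p263) for p in peps}
    return table, pep_map
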