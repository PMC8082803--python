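import numpy as np
import pandas as pd
import pytest

from gestclock.clocks import ClockModel
from gestclock.io_core import BetaMatrix


@pytest.fixture
def toy_clock() -> ClockModel:
    return ClockModel(name="toy", intercept=30.0,
                      weights={"cgA": 10.0, "cgB": -5.0, "cgC": 2.0})


@pytest.fixture
def toy_betas() -> BetaMatrix:
    # two samples over the three toy-clock CpGs plus one non-clock CpG
    values = np.array([
        [0.5, 0.2, 0.1, 0.9],
        [0.6, 0.4, 0.3, 0.1],
    ])
    return BetaMatrix(cpg_ids=["cgA", "cgB", "cgC", "cgX"],
                      sample_ids=["s1", "s2"], values=values)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def random_beta_matrix(rng, n_samples: int, cpgs) -> BetaMatrix:
    values = rng.uniform(0.0, 1.0, (n_samples, len(cpgs)))
    return BetaMatrix(cpg_ids=list(cpgs),
                      sample_ids=[f"s{i}" for i in range(n_samples)],
                      values=values)
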