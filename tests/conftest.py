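import logging

import numpy as np
import pytest
from hypothesis import settings

import qdnet

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

# the suite exercises many degenerate corners on purpose; keep logs quiet
logging.getLogger("qdnet").setLevel(logging.ERROR)


@pytest.fixture
def toy_matrix():
    """4 samples x 4 taxa with distinct row sums."""
    values = np.array([
        [1.0, 2.0, 3.0, 4.0],
        [2.0, 1.0, 1.0, 1.0],
        [5.0, 0.0, 2.0, 3.0],
        [0.5, 0.5, 0.5, 0.5],
    ])
    return qdnet.AbundanceMatrix(values, [f"s{i}" for i in range(4)],
                                 [f"t{j}" for j in range(4)])


@pytest.fixture
def planted():
    """Small planted community with links, reused across stage tests."""
    cfg = qdnet.GeneratorConfig(n_samples=40, n_taxa=8, seed=11, n_partners=2,
                                sigma_log=0.02)
    return qdnet.generate(cfg)
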