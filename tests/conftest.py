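import numpy as np
import pytest

from elmseq import simulate as sim
from elmseq.templates import get_template


@pytest.fixture(scope="session")
def promoter_template():
    return get_template("promoter")


@pytest.fixture(scope="session")
def utr_strong_template():
    return get_template("utr_strong")


@pytest.fixture(scope="session")
def promoter_truth():
    """Small promoter library with planted effects (shared, read-only)."""
    cfg = sim.default_promoter_config(n_variants=800)
    return sim.simulate_library(cfg, seed=101)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_seqs(rng, n, length):
    return ["".join(row) for row in
            np.array(list("ACGT"))[rng.integers(0, 4, size=(n, length))]]
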