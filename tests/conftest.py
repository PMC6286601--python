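import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=60)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def null_cohort():
    """Small null cohort (no insertions), shared across tests."""
    import motifrank as mr
    design = mr.SimDesign(n_sequences=120, length=150, insertions=0, seed=5)
    ids, seqs = mr.gen_ranked_sequences(design)
    return ids, seqs
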