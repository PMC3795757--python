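import pytest

from hetgwas import GenotypeCountTable, ModelSpec

# the paper-style parameter grid used by sweep tests
GRID_MODELS = ["dominant", "multiplicative"]
GRID_PREVALENCES = [0.001, 0.01, 0.05, 0.1]
GRID_MAFS = [0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5]
GRID_RRS = [1.1, 1.2, 1.3, 1.5, 2.0, 5.0, 10.0]


@pytest.fixture
def toy_table() -> GenotypeCountTable:
    """The worked 2x3 example: cases 20/20/10, controls 30/15/5."""
    return GenotypeCountTable((20, 20, 10), (30, 15, 5))


@pytest.fixture
def reference_spec() -> ModelSpec:
    """The running example: multiplicative, K=0.01, q=0.2, rr=2."""
    return ModelSpec("multiplicative", 0.01, 0.2, 2.0)
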