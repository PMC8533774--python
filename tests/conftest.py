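import numpy as np
import pytest

from wdnafld.design import make_design
from wdnafld.diffexpr import CountMatrix


@pytest.fixture(scope="session")
def default_design():
    return make_design()


@pytest.fixture(scope="session")
def small_design():
    """All 15 levels, 3 replicates each: cheap but structurally complete."""
    return make_design(replicates_per_level=3)


def make_counts(values, gene_prefix="g", sample_prefix="s") -> CountMatrix:
    values = np.asarray(values)
    return CountMatrix(
        values,
        [f"{gene_prefix}{i}" for i in range(values.shape[0])],
        [f"{sample_prefix}{j}" for j in range(values.shape[1])],
    )
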