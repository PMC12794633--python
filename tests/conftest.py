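import numpy as np
import pytest

from strokeprog import (
    generate_lesion_case,
    generate_tube_tree,
    symmetric_y_phantom,
)


@pytest.fixture(scope="session")
def y_phantom():
    """Y-shaped tube phantom (3 branches, 3 endpoints, 1 junction) + truth."""
    return generate_tube_tree(symmetric_y_phantom())


@pytest.fixture(scope="session")
def lesion_case():
    """DWI-like phantom with a disk lesion, deterministic."""
    return generate_lesion_case(seed=42, case_id="fix")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
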