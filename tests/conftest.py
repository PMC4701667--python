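import numpy as np
import pytest

from wormbench.patterns import ProjectionTransform


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def t5():
    """Default 5X projection transform."""
    return ProjectionTransform.for_objective(5)


@pytest.fixture
def fine_grid():
    """1 μm/px working grid for geometry-precision checks."""
    return ProjectionTransform(5, 1.0, dmd_shape=(400, 400))
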