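import warnings

import numpy as np
import pytest

from ensemblesdm.grids import GridSpec, LayerKind, RasterLayer, RasterStack

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)
warnings.filterwarnings("ignore", module="sklearn")


@pytest.fixture
def grid5():
    return GridSpec(cell_size=30.0, origin=(0.0, 150.0), n_rows=5, n_cols=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_stack(grid5, rng):
    layers = [
        RasterLayer("a", grid5, rng.normal(size=grid5.shape)),
        RasterLayer("b", grid5, rng.normal(size=grid5.shape)),
        RasterLayer("cat", grid5, rng.integers(0, 3, grid5.shape).astype(float),
                    kind=LayerKind.CATEGORICAL),
    ]
    return RasterStack(layers)


@pytest.fixture
def toy_training():
    """Separable two-variable presence/background table."""
    import pandas as pd

    from ensemblesdm.algorithms import TrainingSet

    rng = np.random.default_rng(7)
    n = 60
    x1 = np.concatenate([rng.normal(2.0, 0.5, n), rng.normal(-2.0, 0.5, n)])
    x2 = rng.normal(0.0, 1.0, 2 * n)
    y = np.concatenate([np.ones(n, int), np.zeros(n, int)])
    return TrainingSet(pd.DataFrame({"x1": x1, "x2": x2}), y)
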