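import numpy as np
import pytest

from unfoldirt import (
    ModelSpec,
    ParamSet,
    ResponseData,
    build_grid,
    default_starts,
    gen_items,
    gen_responses,
)

TAU = np.array([-1.10, -0.72, -0.30])


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture
def small_grid():
    """Coarse 1-D grid keeping toy likelihood computations fast."""
    return build_grid((-4, 4), 21, 1)


@pytest.fixture
def toy_ggum():
    """Tiny UM8 dataset: 6 persons, 3 four-point items."""
    spec = ModelSpec.from_kernel("UM8", 3, 3)
    params = ParamSet(
        delta=np.array([-1.0, 0.2, 1.1]),
        alpha=np.array([0.9, 1.1, 1.0]),
        thresh=np.tile(TAU, (3, 1)),
    )
    codes = np.array([
        [0, 1, 3],
        [2, 3, 1],
        [3, 2, 0],
        [1, 1, 2],
        [3, 3, 3],
        [0, 0, 1],
    ])
    return spec, params, ResponseData(codes, 3)


def random_paramset(spec, rng):
    """Random admissible parameters for property tests."""
    I, C = spec.n_items, spec.n_categories
    delta = rng.uniform(-2.5, 2.5, I)
    alpha = rng.uniform(0.5, 2.0, I) if spec.alpha_free else np.ones(I)
    if spec.family == "ggum":
        tvals = rng.uniform(-1.5, 0.5, C)
    elif spec.family == "unit":
        tvals = rng.uniform(0.1, 0.8, 1)
    else:
        tvals = rng.uniform(0.3, 2.0, C)
    if spec.family == "mum":
        thresh = np.tile(tvals, (spec.n_dims, 1))
    elif spec.threshold_mode == "item":
        thresh = np.tile(tvals, (I, 1)) * rng.uniform(0.8, 1.2, (I, 1))
    else:
        thresh = tvals
    corr = None
    if spec.n_dims > 1:
        corr = rng.uniform(-0.3, 0.3, spec.n_dims * (spec.n_dims - 1) // 2)
    return ParamSet(delta, alpha, thresh, 1.0, corr)
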