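import numpy as np
import pytest

import mammotex as mx
from mammotex.modeling import ModelConfig


@pytest.fixture(scope="session")
def phantom():
    """One deterministic left-breast phantom with ground truth."""
    spec = mx.PhantomSpec(seed=11)
    return mx.generate_phantom(spec)


@pytest.fixture(scope="session")
def segmented(phantom):
    img, truth = phantom
    return img, truth, mx.segment_all(img)


@pytest.fixture(scope="session")
def anatomy(segmented):
    img, truth, seg = segmented
    an = mx.standardize_orientation(img, seg)
    return img, truth, mx.define_quadrants(an, f=0.6)


@pytest.fixture(scope="session")
def grid(anatomy):
    img, truth, an = anatomy
    return mx.build_polar_grid(an, D_mm=6.3)


@pytest.fixture(scope="session")
def desk_model_config():
    """Small nested-CV budget for unit-scale cohorts."""
    return ModelConfig(outer_folds=5, inner_folds=3, l1_ratios=(0.2, 0.5, 0.8),
                       n_penalties=8, n_bootstrap=200)


@pytest.fixture(autouse=True)
def _quiet_warnings(recwarn):
    """Convergence warnings from deliberately capped saga iterations are
    expected on noise-only unit problems."""
    import warnings
    from sklearn.exceptions import ConvergenceWarning

    warnings.simplefilter("ignore", ConvergenceWarning)
    yield


def rng(seed=0):
    return np.random.default_rng(seed)
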