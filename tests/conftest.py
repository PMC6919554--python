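import numpy as np
import pytest

from aclspeech.acl_core import ClassificationSet, ReconstructionSet


def random_instance(seed, n=40, d=10, m=30, noise=0.3):
    """Small random classification + reconstruction problem with linear truth."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    w_true = rng.standard_normal(d)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-X @ w_true))).astype(int)
    if len(set(y)) < 2:  # guarantee both classes
        y[0], y[1] = 0, 1
    Xr = rng.standard_normal((m, d))
    a = Xr @ w_true + noise * rng.standard_normal(m)
    return ClassificationSet(X, y), ReconstructionSet(Xr, a), w_true


@pytest.fixture
def tiny_instance():
    return random_instance(0, n=20, d=5, m=15)
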