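import numpy as np
import pytest

from polymag import ModelParams
from polymag.builder import build_system


@pytest.fixture(scope="session")
def params_q6() -> ModelParams:
    return ModelParams(q=6.0, seed=7)


@pytest.fixture(scope="session")
def system_q6(params_q6):
    """Full-resolution q=6 assembly + MNP load (shared, read-only)."""
    return build_system(params_q6, orientation_seed=11)


@pytest.fixture(scope="session")
def coarse_params() -> ModelParams:
    """Coarse-mesh q=6 system for cheap force/topology tests."""
    return ModelParams(q=6.0, seed=3, coarsen=2.5)


@pytest.fixture(scope="session")
def coarse_system(coarse_params):
    return build_system(coarse_params, orientation_seed=5)


def numerical_gradient(f, x, h=1e-6):
    """Central-difference gradient of scalar f over an (N, 3) array."""
    g = np.zeros_like(x)
    for i in range(x.shape[0]):
        for d in range(3):
            xp = x.copy()
            xp[i, d] += h
            xm = x.copy()
            xm[i, d] -= h
            g[i, d] = (f(xp) - f(xm)) / (2 * h)
    return g
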