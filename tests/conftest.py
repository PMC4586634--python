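import warnings

import numpy as np
import pytest

from miscount import (
    McmcSettings,
    ModelSpec,
    ObservedDataset,
    ParameterState,
    PriorSpec,
)

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", message=".*ArviZ.*")


@pytest.fixture
def small_dataset() -> ObservedDataset:
    """Eight units, two patterns, moderate counts, with clusters."""
    rng = np.random.default_rng(11)
    x = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
    t = np.full(8, 50.0)
    lam = np.exp(-1.0 + 0.5 * x)
    mu = np.exp(-2.0 - 0.3 * x)
    w1 = rng.poisson(t * lam)
    w2 = rng.poisson(t * mu)
    return ObservedDataset(
        w1=w1, w2=w2, t=t, x=x, z=np.empty((8, 0)),
        cluster=np.arange(8),
    )


@pytest.fixture
def fixed_spec() -> ModelSpec:
    return ModelSpec(effects="fixed", misclass="unknown", p=0)


@pytest.fixture
def tight_priors() -> PriorSpec:
    return PriorSpec(se_beta=(45.0, 5.0), sp_beta=(40.0, 10.0))


@pytest.fixture
def quick_settings() -> McmcSettings:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return McmcSettings(n_chains=1, n_burn=400, n_keep=400, seed=5)


def make_state(beta, gamma, **kw) -> ParameterState:
    return ParameterState(beta=np.asarray(beta, float),
                          gamma=np.asarray(gamma, float), **kw)
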