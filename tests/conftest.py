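import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from depgp import (
    AffinityMatrix,
    HyperParams,
    KernelParams,
    SamplerConfig,
    ScenarioConfig,
    SensitivityMatrix,
    generate,
    run_mcmc,
)

DEFAULT_KP = KernelParams(0.155, 0.126)


@pytest.fixture(scope="session")
def default_hp():
    return HyperParams(kernel=DEFAULT_KP)


@pytest.fixture(scope="session")
def default_scenario():
    """The standard synthetic scenario (generator defaults)."""
    return generate(ScenarioConfig())


@pytest.fixture(scope="session")
def default_posterior(default_scenario, default_hp):
    """Six chains of 120 iterations (20 burn-in) on the standard scenario.

    Shared across the recovery and convergence tests; ~5 s to produce.
    """
    return run_mcmc(default_scenario.X, default_scenario.Y, default_hp,
                    SamplerConfig(seed=0))


def make_small_instance(seed, D=6, P=2, S=2, x_missing=0.3, y_missing=0.2):
    """A tiny random instance with missingness in both X and Y."""
    rng = np.random.default_rng(seed)
    Xv = rng.uniform(size=(D, P))
    pres = rng.uniform(size=(D, P)) < 1.0 - x_missing
    pres[0, :] = True  # keep every column identifiable
    X = AffinityMatrix(np.where(pres, Xv, np.nan), pres,
                       [f"d{i}" for i in range(D)], [f"p{i}" for i in range(P)])
    Yv = rng.normal(size=(D, S))
    obs = rng.uniform(size=(D, S)) < 1.0 - y_missing
    obs[:2, :] = True
    Y = SensitivityMatrix(np.where(obs, Yv, np.nan), obs,
                          [f"d{i}" for i in range(D)], [f"s{i}" for i in range(S)])
    return X, Y


@pytest.fixture
def small_instance():
    return make_small_instance(seed=42)
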