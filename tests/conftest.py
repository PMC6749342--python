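import numpy as np
import pytest

from prefall import (
    AOParams,
    ATBAParams,
    PerturbationConfig,
    foot_config,
    generate_trial,
    shank_config,
)


@pytest.fixture(scope="session")
def shank_cfg():
    return shank_config(seed=11)


@pytest.fixture(scope="session")
def foot_cfg():
    return foot_config(seed=11)


@pytest.fixture(scope="session")
def shank_trial(shank_cfg):
    """One perturbed shank trial: 15 s steady walking, arrest at 15 s."""
    return generate_trial(shank_cfg, PerturbationConfig())


@pytest.fixture(scope="session")
def shank_gains():
    """Learning gains selected for the shank channel."""
    return AOParams(k_P=20.0, k_A=1.0)


@pytest.fixture(scope="session")
def default_atba():
    return ATBAParams(w=400, k=3.5, r=6)


def brute_force_window_stats(e: np.ndarray, w: int):
    """O(n*w) reference for the detector's windowed mean/sd (population sd),
    computed from the w samples strictly before each frame."""
    n = len(e)
    mu = np.full(n, np.nan)
    sigma = np.full(n, np.nan)
    for t in range(w, n):
        win = e[t - w:t]
        mu[t] = np.mean(win)
        sigma[t] = np.std(win)
    return mu, sigma
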