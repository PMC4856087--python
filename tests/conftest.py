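import numpy as np
import pandas as pd
import pytest

from degscan import (
    CountMatrix,
    SimulationConfig,
    estimate_size_factors,
    simulate_study,
)


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic study at the default configuration."""
    cfg = SimulationConfig(seed=0)
    annotation, truth, cm = simulate_study(cfg)
    return cfg, annotation, truth, cm


@pytest.fixture()
def small_cm():
    """A tiny deterministic count matrix with two groups of three samples."""
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.poisson(50, size=(40, 6)),
        index=[f"g{i}" for i in range(40)],
        columns=[f"s{i}" for i in range(6)],
    )
    groups = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
    cm = CountMatrix(counts, groups)
    estimate_size_factors(cm)
    return cm


def nb_counts(rng, mean, alpha, size):
    """Reference NB sampler used by oracle simulations in the tests."""
    if alpha <= 0:
        return rng.poisson(mean, size)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mean), size)
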