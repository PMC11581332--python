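import numpy as np
import pandas as pd
import pytest

from hrqolseg.simulate import default_config, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-participant synthetic cohort (complete, fixed seed)."""
    cfg = default_config(seed=11, n=400)
    table, truth = generate_cohort(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def default_cohort():
    """The full-size default cohort (n=1697, fixed seed)."""
    cfg = default_config(seed=1)
    table, truth = generate_cohort(cfg)
    return cfg, table, truth


def simulate_multinomial(coefs: dict, X: pd.DataFrame, categories, rng) -> np.ndarray:
    """Draw 3-category outcomes from a multinomial logit ground truth.

    ``coefs[cat]`` maps design column -> coefficient for each
    non-reference category; the first category is the reference.
    """
    eta = np.zeros((len(X), len(categories)))
    for j, cat in enumerate(categories[1:], start=1):
        for col, b in coefs[cat].items():
            eta[:, j] += b * X[col].to_numpy(dtype=float)
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(len(X))
    idx = (u[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
    return np.asarray(categories, dtype=object)[idx]
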