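import numpy as np
import pytest

from bintrial import (
    ModelSpec,
    SimConfig,
    TrialTable,
    encode,
    simulate_trial,
)


@pytest.fixture(scope="session")
def default_trial():
    """One default-configuration synthetic trial (342 participants)."""
    return simulate_trial(SimConfig(seed=20260901))


@pytest.fixture(scope="session")
def default_table(default_trial):
    return TrialTable(default_trial.table)


@pytest.fixture(scope="session")
def risk_design(default_table):
    return encode(default_table, "risk")


def tiny_logistic_spec(n=12, k=2, seed=0, **kwargs):
    """Small random hierarchical logistic spec for numerics tests."""
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = rng.binomial(1, 0.5, size=n).astype(float)
    center = rng.integers(0, k, size=n)
    center[:k] = np.arange(k)  # every center occupied
    return ModelSpec(kind="bernoulli_logit", X=X, y=y,
                     center_index=center, k=k, **kwargs)


def tiny_gaussian_spec(n=12, k=2, seed=0, **kwargs):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = rng.normal(size=n)
    center = rng.integers(0, k, size=n)
    center[:k] = np.arange(k)
    return ModelSpec(kind="gaussian", X=X, y=y,
                     center_index=center, k=k, **kwargs)


def finite_difference_gradient(f, theta, h=1e-5):
    theta = np.asarray(theta, float)
    g = np.empty_like(theta)
    for i in range(len(theta)):
        e = np.zeros_like(theta)
        e[i] = h
        g[i] = (f(theta + e) - f(theta - e)) / (2 * h)
    return g
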