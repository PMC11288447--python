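"""Shared fixtures: small training batches and a trained Kepler k=2 network.

The trained network is session-scoped because several property tests
(sensitivity of latents to m1, latent-space fitting) probe the same trained
encoder/decoder; training it once keeps the suite fast.
"""

import numpy as np
import pytest

from fixfit import bottleneck, datagen


@pytest.fixture(scope="session")
def kepler_batch():
    """Small eccentricity-filtered Kepler batch (deterministic)."""
    return datagen.generate_kepler_batch(n_target=1200, seed=3)


@pytest.fixture(scope="session")
def kepler_k2_model(kepler_batch):
    """A k=2 bottleneck network trained on the Kepler batch at a small budget."""
    cfg = bottleneck.TrainConfig(epochs=1000, patience=150, seed=0)
    res = bottleneck.train(bottleneck.NetworkSpec.kepler(2), kepler_batch, cfg)
    # the latent representation is only meaningful if the fit is decent
    assert res.min_val_mse < 5e-3
    return res.model


@pytest.fixture(scope="session")
def rank_task():
    """Synthetic rank-2 regression task: outputs depend on 2 linear combos of 4 inputs."""
    return make_rank_task(rank=2, seed=5)


def make_rank_task(rank: int, n: int = 1536, n_inputs: int = 4, n_outputs: int = 12, seed: int = 0):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n_inputs, rank))
    B = rng.standard_normal((rank, n_outputs))
    X = rng.random((n, n_inputs))
    Y = np.tanh(X @ A) @ B  # nonlinear in the rank-r subspace only
    n_val = n // 8
    return (X[n_val:], Y[n_val:], X[:n_val], Y[:n_val])
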