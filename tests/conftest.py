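import numpy as np
import pytest

from visemnet import (
    RunConfig,
    gen_feature_norms,
    gen_visual_embeddings,
    init_network,
    run_pipeline,
    svd_reduce,
    train_bptt,
)


@pytest.fixture(scope="session")
def tiny_norms():
    """Small category-structured norms shared by fast unit tests."""
    return gen_feature_norms(
        n_concepts=24, n_categories=4, features_per_concept=8, seed=7
    )


@pytest.fixture(scope="session")
def tiny_trained(tiny_norms):
    """A trained network on the small norms, with its inputs."""
    emb = gen_visual_embeddings(tiny_norms, n_dims=12, seed=7)
    inputs, _ = svd_reduce(emb, 12)
    net = init_network(12, tiny_norms.matrix.shape[1], seed=7)
    trained, epochs, hist = train_bptt(net, inputs, tiny_norms.matrix)
    assert hist.converged
    return {"net": trained, "inputs": inputs, "norms": tiny_norms, "history": hist}


@pytest.fixture(scope="session")
def toy_task():
    """3 orthogonal items, 6 features (2 per item, disjoint)."""
    inputs = np.eye(3)
    targets = np.zeros((3, 6))
    targets[0, :2] = targets[1, 2:4] = targets[2, 4:] = 1.0
    return inputs, targets


@pytest.fixture(scope="session")
def default_runs():
    """Five full pipeline runs under the default study conditions.

    Shared across the acceptance tests for feature dynamics, stage
    recovery and gradient shapes; each run trains the attractor network,
    builds the 26-stage trajectory and analyses a 12-subject synthetic
    brain at snr 2.
    """
    return [
        run_pipeline(RunConfig(seed=seed, gradient_n_perm=500))
        for seed in (1, 2, 3, 4, 5)
    ]
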