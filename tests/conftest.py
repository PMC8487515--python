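import numpy as np
import pytest

import lacfnforest as lf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def reduced_budgets():
    """Desk-scale evolution/PSO budgets shared by the training tests."""
    return lf.reduced_budget(seed=1)


@pytest.fixture(scope="session")
def tiny_budgets():
    """Minimal budgets for tests that only exercise plumbing, not accuracy."""
    evo = lf.EvolutionConfig(population_size=8, max_generations=3, patience=2,
                             max_depth=3, seed=0)
    pso = lf.PSOConfig(swarm_size=6, max_iters=5, final_iters=10, seed=0)
    return evo, pso


@pytest.fixture(scope="session")
def easy_dataset():
    """Well-separated 4-class expression-like data, z-scored, no missingness."""
    spec = lf.SyntheticSpec(
        n_samples=120, n_genes=20, n_classes=4, n_informative=10,
        effect_size=2.0, missing_rate=0.0, seed=3,
    )
    matrix, labels, truth = lf.generate_classification_data(spec)
    X = lf.zscore_normalize(matrix).values
    return X, labels.as_indices(), truth


@pytest.fixture(scope="session")
def trained_small_model(easy_dataset, tiny_budgets):
    """One small trained laminar model reused across structural tests."""
    X, y, _ = easy_dataset
    evo, pso = tiny_budgets
    cfg = lf.LaminarConfig(seed=2, max_cascade_levels=2)
    model, routing = lf.train_laminar(X, y, cfg, evo, pso)
    return model, routing, X, y


def random_valid_tree(rng, input_dim=8, fs=None, max_depth=4):
    fs = fs or lf.F1
    return lf.random_tree(fs, input_dim, rng, max_depth=max_depth)
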