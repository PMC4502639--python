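import numpy as np
import pandas as pd
import pytest

from stagenet.simdata import SimConfig, simulate_dataset


def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    return len(a & b) / len(a | b) if a | b else 0.0


SMALL_CONFIG = SimConfig(
    n_genes=300,
    n_normal=30,
    n_tumor_early=40,
    n_tumor_late=40,
    n_batches=2,
    n_modules=3,
    module_sizes=(50, 40, 35),
    stage_module_index=1,
    stage_effect=0.5,
    n_de_genes=150,
    seed=123,
)


@pytest.fixture(scope="session")
def small_ds():
    """A small planted dataset shared across read-only tests."""
    return simulate_dataset(SMALL_CONFIG)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def planted_blocks(n_samples=100, block=50, n_noise=20, seed=0, noise_in_block=0.0):
    """Two perfectly correlated gene blocks plus independent noise genes."""
    r = np.random.default_rng(seed)
    f1, f2 = r.standard_normal(n_samples), r.standard_normal(n_samples)
    X = np.vstack(
        [
            np.outer(np.ones(block), f1)
            + noise_in_block * r.standard_normal((block, n_samples)),
            np.outer(np.ones(block), f2)
            + noise_in_block * r.standard_normal((block, n_samples)),
            r.standard_normal((n_noise, n_samples)),
        ]
    )
    genes = [f"g{i:03d}" for i in range(2 * block + n_noise)]
    return pd.DataFrame(X, index=genes), genes[:block], genes[block : 2 * block]
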