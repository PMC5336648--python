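import numpy as np
import pytest

from osgabi import LoadingsSpec, ModelParams
from osgabi.core import contract_psi, lambda_shared


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_binary_loadings(p, q, rng):
    """Binary row-stochastic p x q matrix with no empty variable cluster."""
    labels = np.concatenate([np.arange(q), rng.integers(0, q, size=p - q)])
    rng.shuffle(labels)
    lam = np.zeros((p, q))
    lam[np.arange(p), labels] = 1.0
    return lam


def random_params(model, G, p, q, rng):
    """Arbitrary valid ModelParams for oracle comparisons."""
    n_mats = 1 if lambda_shared(model) else G
    spec = LoadingsSpec(
        matrices=[random_binary_loadings(p, q, rng) for _ in range(n_mats)]
    )
    pi = rng.dirichlet(np.full(G, 5.0))
    mu = rng.normal(0.0, 3.0, size=(G, p))
    psi_gp = rng.uniform(0.3, 2.5, size=(G, p))
    return ModelParams(
        model=model, G=G, pi=pi, mu=mu, loadings=spec,
        psi=contract_psi(psi_gp, model),
    )


@pytest.fixture
def canonical_spec():
    """p=4, q=2 shared Lambda with two contiguous blocks."""
    return LoadingsSpec(matrices=[np.array(
        [[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]]
    )])
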