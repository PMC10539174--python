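import numpy as np
import pytest

import lineagescope as ls


@pytest.fixture(scope="session")
def small_dataset():
    """A small full experiment with all condition effects injected."""
    cfg = ls.paper_like(cells_per_sample=200, n_genes=800, seed=0)
    return ls.simulate_experiment(cfg)


@pytest.fixture(scope="session")
def small_null_dataset():
    cfg = ls.null_experiment(cells_per_sample=200, n_genes=800, seed=0)
    return ls.simulate_experiment(cfg)


@pytest.fixture(scope="session")
def preprocessed(small_dataset):
    """(normalized, hvg, graph, pseudotime, unreachable) for the small
    experiment."""
    return ls.preprocess_dataset(small_dataset, n_hvg=300, n_pcs=20, k=15)


@pytest.fixture(scope="session")
def midsize_fate_run():
    """A mid-size experiment pushed through preprocess + fate, shared by the
    trajectory-quality tests."""
    cfg = ls.paper_like(cells_per_sample=600, n_genes=1500, seed=0)
    ds = ls.simulate_experiment(cfg)
    norm, hvg, graph, pt, unreach = ls.preprocess_dataset(
        ds, n_hvg=500, n_pcs=30, k=25)
    fate, table, model = ls.run_fate(ds, graph, pt, beta=5.0,
                                     terminal_quantile=0.9, scale=None)
    return dict(ds=ds, normalized=norm, graph=graph, pt=pt, fate=fate,
                table=table, model=model)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
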