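import numpy as np
import pytest

from postgwas import synth


def make_panel(seed=0, n=1000, block_sizes=(20, 20), rho=0.6, causal=(), **kw):
    """One-call panel + truth + GWAS factory used across the suite."""
    config = synth.SimConfig(
        seed=seed,
        n_individuals=n,
        n_variants=sum(block_sizes),
        block_sizes=list(block_sizes),
        within_block_rho=rho,
        causal_spec=tuple(causal),
        **kw,
    )
    panel = synth.simulate_ld_panel(config)
    truth = synth.make_truth(config)
    return config, panel, truth


@pytest.fixture(scope="session")
def basic_panel():
    config, panel, truth = make_panel(seed=11, n=1500, block_sizes=(20, 20, 20),
                                      causal=((10, 0.3),))
    gwas = synth.simulate_gwas_sumstats(panel, truth, config)
    return config, panel, truth, gwas


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
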