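import pytest

from cernaforge.synthdata import (
    SimConfig,
    generate_expression,
    generate_interactions,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A small but fully-featured synthetic world."""
    return SimConfig(seed=11, n_lnc=60, n_mir=40, n_mrna=300, n_triplets=4)


@pytest.fixture(scope="session")
def bundle(small_cfg):
    return generate_expression(small_cfg)


@pytest.fixture(scope="session")
def noisefree_cfg() -> SimConfig:
    """Sources reproduce the planted edges exactly (recall 1, no false edges)."""
    return SimConfig(seed=11, n_lnc=60, n_mir=40, n_mrna=300, n_triplets=4,
                     source_recall=1.0, source_fpr=0.0)


@pytest.fixture(scope="session")
def noisefree_world(noisefree_cfg):
    b = generate_expression(noisefree_cfg)
    return noisefree_cfg, b, generate_interactions(noisefree_cfg, b)
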