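import pytest

from exondsi import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 150-gene synthetic dataset with planted DE and AS (fixed seed)."""
    cfg = SimConfig(n_genes=150, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_dataset():
    """A dataset without planted structure or background probesets."""
    cfg = SimConfig(
        n_genes=60, seed=7, de_fraction=0.0, as_fraction=0.0,
        background_fraction=0.0,
    )
    return simulate_dataset(cfg)
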