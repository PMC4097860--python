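import numpy as np
import pytest

from triplome.config import SimulationConfig


@pytest.fixture
def tiny_config():
    """Small but complete simulation configuration for fast tests."""
    return SimulationConfig(
        seed=42,
        n_chromosomes=1,
        chrom_length_bp=80_000,
        n_ancestral_genes=12,
        lambda_length_bp=5_000,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
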