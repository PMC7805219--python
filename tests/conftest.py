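import numpy as np
import pytest

from tefamkit.consensus import default_matrix
from tefamkit.simulate import FamilySpec, SimConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """One 400-bp class II family, 15 copies at 10% divergence, 30-kb genome."""
    cfg = SimConfig(
        seed=42,
        genome_length=30_000,
        families=[
            FamilySpec(name="TIRX", kind="class2_tir", ancestral_length=400,
                       copy_number=15, mean_divergence=0.10),
        ],
    )
    genome, truth = simulate(cfg)
    return cfg, genome, truth


@pytest.fixture(scope="session")
def standard_family_sim():
    """The standard single-family conditions: 1,000-bp class II ancestor,
    50 copies, 15% divergence, CpG transitions x10."""
    cfg = SimConfig(
        seed=7,
        genome_length=80_000,
        families=[
            FamilySpec(name="FAM", kind="class2_tir", ancestral_length=1000,
                       copy_number=50, mean_divergence=0.15),
        ],
    )
    genome, truth = simulate(cfg)
    return cfg, genome, truth


@pytest.fixture(scope="session")
def matrix15():
    return default_matrix(0.15, 2.0, 10.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
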