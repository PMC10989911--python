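import numpy as np
import pytest
from hypothesis import settings

from panfactor import (
    GeneFamilyMatrix,
    PangenomeStats,
    SimConfig,
    simulate_dataset,
    synthetic_membership,
)

settings.register_profile("suite", deadline=None, max_examples=30, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def tiny_matrix() -> GeneFamilyMatrix:
    return GeneFamilyMatrix(
        family_ids=["gf1", "gf2", "gf3"],
        sample_ids=["s1", "s2"],
        values=np.array([[12.0, 0.0], [30.5, 44.25], [0.0, 101.0]]),
        units="rpkm",
    )


@pytest.fixture(scope="session")
def small_mixture():
    """A small 3-strain Poisson mixture with its membership table."""
    cfg = SimConfig(n_families=400, n_strains=3, n_samples=10, seed=7)
    D, truth = simulate_dataset(cfg)
    stats = synthetic_membership(truth)
    return D, truth, stats


@pytest.fixture(scope="session")
def noiseless_mixture():
    """Well-separated noiseless 3-strain mixture for oracle-recovery checks."""
    cfg = SimConfig(
        n_families=500,
        n_strains=3,
        n_samples=12,
        min_pairwise_jaccard=0.3,
        noise_model="none",
        seed=11,
    )
    D, truth = simulate_dataset(cfg)
    stats = synthetic_membership(truth)
    return D, truth, stats


@pytest.fixture
def toy_stats() -> PangenomeStats:
    rng = np.random.default_rng(3)
    membership = (rng.random((60, 4)) < 0.7).astype(int)
    membership[:20] = 1  # core
    return PangenomeStats(
        family_ids=[f"gf{i}" for i in range(60)],
        genome_ids=["g1", "g2", "g3", "g4"],
        membership=membership,
    )
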