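import numpy as np
import pytest

from epiqtl.lmm import KinshipMatrix, compute_kinship
from epiqtl.simulate import (
    PopulationConfig,
    TraitSimConfig,
    generate_study_bundle,
    simulate_structured_genotypes,
)


@pytest.fixture(scope="session")
def panel():
    """Default-sized structured panel: 135 accessions x 2000 SNPs."""
    return simulate_structured_genotypes(
        PopulationConfig(n_individuals=135, n_snps=2000, seed=5)
    )


@pytest.fixture(scope="session")
def K_S(panel):
    return compute_kinship(panel.matrix.T.astype(float), role="global_snp")


@pytest.fixture(scope="session")
def small_panel():
    """Small panel for cheap tests: 40 accessions x 300 SNPs."""
    return simulate_structured_genotypes(
        PopulationConfig(n_individuals=40, n_snps=300, seed=1)
    )


@pytest.fixture(scope="session")
def small_K(small_panel):
    return compute_kinship(small_panel.matrix.T.astype(float), role="global_snp")


def make_full_rank_kinship(n, seed, role="global_snp"):
    """Generic positive-definite similarity matrix (no null directions)."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(n, 2 * n))
    K = A @ A.T / (2 * n) + 0.3 * np.eye(n)
    K /= np.diag(K).mean()
    return KinshipMatrix(role=role, matrix=K)


@pytest.fixture
def full_rank_kinship():
    return make_full_rank_kinship


@pytest.fixture(scope="session")
def tiny_bundle(tmp_path_factory):
    """Small on-disk study bundle shared by IO/pipeline tests."""
    out = tmp_path_factory.mktemp("bundle")
    pop = PopulationConfig(n_individuals=30, n_snps=200, seed=2)
    traits = [
        TraitSimConfig(model=m, n_small_effects=200, seed=10 + i, link_strength=0.6)
        for i, m in enumerate(["I", "II", "III", "IV", "I", "III"])
    ]
    paths = generate_study_bundle(pop, traits, out, n_background_bins=10)
    return {"paths": paths, "pop": pop, "traits": traits, "dir": out}
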