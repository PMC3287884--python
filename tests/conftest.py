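import numpy as np
import pandas as pd
import pytest

from gensem.simulate import (
    GeneConfig,
    GenotypeMatrix,
    PopulationConfig,
    TraitModel,
    simulate_genotypes,
    simulate_replicates,
)


@pytest.fixture(scope="session")
def toy_genotypes() -> GenotypeMatrix:
    """6 individuals x 4 SNPs: 2 rare (MAF < 0.05 would be too strict at
    n=6, so the rare threshold is passed explicitly in tests), 2 common."""
    values = np.array(
        [
            [0, 0, 1, 0],
            [0, 0, 2, 1],
            [0, 1, 0, 2],
            [0, 0, 1, 1],
            [2, 0, 0, 0],
            [0, 0, 2, 1],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        values,
        [f"I{i}" for i in range(6)],
        ["rareA", "rareB", "comA", "comB"],
        {"rareA": "G1", "rareB": "G1", "comA": "G1", "comB": "G2"},
    )


@pytest.fixture(scope="session")
def small_study():
    """Small two-gene study with one causal gene, three replicates."""
    genes = [
        GeneConfig("CAUS", ("c1", "c2", "c3"), (0.3, 0.25, 0.2),
                   causal_effects=(0.5, 0.4, 0.0), ld_rho=0.6),
        GeneConfig("NULL", ("n1", "n2"), (0.3, 0.1), ld_rho=0.5),
    ]
    pops = PopulationConfig(sizes=(150, 150), differentiation=0.05)
    geno = simulate_genotypes(pops, genes, seed=11)
    return simulate_replicates(geno, TraitModel(residual_sd=1.0), genes, 3, seed=11)


@pytest.fixture(scope="session")
def one_factor_data():
    """n=800 draws from a known one-factor model with three indicators."""
    rng = np.random.default_rng(7)
    n = 800
    eta = rng.standard_normal(n)
    lam = np.array([1.0, 0.8, 0.6])
    theta = np.array([0.5, 0.4, 0.3])
    y = eta[:, None] * lam + rng.standard_normal((n, 3)) * np.sqrt(theta)
    return pd.DataFrame(y, columns=["y1", "y2", "y3"])
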