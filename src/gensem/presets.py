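"""Default study configuration.

The default synthetic study mirrors the printed dimensions of the
exon-sequencing design it emulates: 697 unrelated individuals from 7
populations, 9 causal genes carrying 39 causal SNPs (a mix of common,
rare and one private variant), plus 12 non-causal decoy genes; the
normally distributed trait Q1 is driven additively by the causal SNPs
and by Age, Sex and Smoking.  Total SNP count (93) is deliberately far
below the real study's 24,487 so everything runs at desk scale.
"""

from __future__ import annotations

from .simulate import (
    GeneConfig,
    PopulationConfig,
    ReplicateSet,
    TraitModel,
    simulate_genotypes,
    simulate_replicates,
)

__all__ = [
    "CAUSAL_GENES",
    "default_population_config",
    "default_gene_configs",
    "default_trait_model",
    "default_study",
]

# per-gene base effect (trait units per minor allele at the strongest SNP);
# FLT1-like gene deliberately strongest
_GENE_EFFECTS = {
    "FLT1": 0.40,
    "KDR": 0.30,
    "ARNT": 0.28,
    "VEGFA": 0.28,
    "VEGFC": 0.26,
    "FLT4": 0.26,
    "HIF3A": 0.24,
    "ELAVL4": 0.24,
    "HIF1A": 0.18,  # weakest by design: its path is expected to be unstable
}
CAUSAL_GENES = tuple(_GENE_EFFECTS)

# genes with 5 causal SNPs; the rest have 4 causal + 1 neutral (39 causal total)
_FIVE_CAUSAL = ("FLT1", "KDR", "ARNT")
_MAFS = (0.35, 0.25, 0.15, 0.02, 0.01)
_REL_EFFECTS = (1.0, 0.8, 0.6, 2.0, 2.5)  # rare SNPs get larger per-allele effects


def default_population_config() -> PopulationConfig:
    return PopulationConfig(sizes=(100, 100, 100, 100, 100, 100, 97), differentiation=0.1)


def default_gene_configs() -> list[GeneConfig]:
    genes = []
    for name, base in _GENE_EFFECTS.items():
        snps = tuple(f"{name}_S{i + 1}" for i in range(5))
        effects = [base * r for r in _REL_EFFECTS]
        if name not in _FIVE_CAUSAL:
            effects[2] = 0.0  # neutral mid-frequency SNP
        private = (snps[4],) if name == "HIF1A" else ()
        genes.append(
            GeneConfig(
                gene_name=name,
                snp_names=snps,
                ancestral_mafs=_MAFS,
                causal_effects=tuple(effects),
                ld_rho=0.75,
                private_snps=private,
            )
        )
    for d in range(1, 13):
        name = f"DECOY{d:02d}"
        genes.append(
            GeneConfig(
                gene_name=name,
                snp_names=tuple(f"{name}_S{i + 1}" for i in range(4)),
                ancestral_mafs=(0.25, 0.15, 0.03, 0.01),
                ld_rho=0.5,
            )
        )
    return genes


def default_trait_model() -> TraitModel:
    return TraitModel(
        intercept=0.0,
        age_effect=0.03,
        sex_effect=0.60,
        smoke_effect=0.65,
        residual_sd=1.0,
    )


def default_study(seed: int, n_replicates: int = 100) -> ReplicateSet:
    """The full default study: fixed genotypes, ``n_replicates`` trait draws."""
    genes = default_gene_configs()
    genotypes = simulate_genotypes(default_population_config(), genes, seed)
    return simulate_replicates(genotypes, default_trait_model(), genes, n_replicates, seed)
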