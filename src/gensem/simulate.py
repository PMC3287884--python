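"""Synthetic multi-population exome-style study generator.

Emulates the structure of the GAW17-style unrelated-individuals design:
a fixed genotype matrix of minor-allele counts over several ancestral
populations, a normally distributed quantitative trait driven additively
by a known set of causal SNPs plus covariates (Age, Sex, Smoking), and a
replicate structure in which genotypes stay fixed while phenotypes are
redrawn.

Population differentiation follows the Balding-Nichols model: for a
locus with ancestral minor-allele frequency ``p`` and drift parameter
``F`` in [0, 1), each population's frequency is drawn from
``Beta(p(1-F)/F, (1-p)(1-F)/F)``, which has mean ``p`` and variance
``F p (1-p)``.  Genotypes are sampled under Hardy-Weinberg equilibrium
(two allele draws per individual).  Within a gene, allele draws may be
correlated across SNPs through a Gaussian copula (``ld_rho``), producing
linkage-disequilibrium-like correlation while keeping every marginal
genotype Binomial(2, p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PopulationConfig",
    "GeneConfig",
    "TraitModel",
    "GenotypeMatrix",
    "ReplicateSet",
    "draw_population_freqs",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_replicates",
]

PHENOTYPE_COLUMNS = ["IID", "Q1", "Age", "Sex", "Smoke", "Pop"]


@dataclass(frozen=True)
class PopulationConfig:
    """Sample sizes and drift for the ancestral populations.

    ``differentiation`` is the Balding-Nichols F: 0 means every
    population shares the ancestral allele frequency.
    """

    sizes: tuple[int, ...] = (100, 100, 100, 100, 100, 100, 97)
    differentiation: float = 0.1

    def __post_init__(self) -> None:
        if len(self.sizes) < 1 or any(s <= 0 for s in self.sizes):
            raise ValueError("population sizes must all be positive")
        f = self.differentiation
        if not (math.isfinite(f) and 0.0 <= f < 1.0):
            raise ValueError(f"differentiation must be in [0, 1), got {f}")

    @property
    def n_populations(self) -> int:
        return len(self.sizes)

    @property
    def n_individuals(self) -> int:
        return int(sum(self.sizes))


@dataclass(frozen=True)
class GeneConfig:
    """One gene: its SNPs, ancestral MAFs, and per-SNP additive trait effects.

    ``causal_effects`` are in trait units per minor allele (0 for a
    non-causal SNP).  ``ld_rho`` is the Gaussian-copula correlation of
    allele draws across the gene's SNPs (0 = independent SNPs).
    ``private_snps`` names SNPs realised as singleton carriers: exactly
    one heterozygous individual, everyone else homozygous major.
    """

    gene_name: str
    snp_names: tuple[str, ...]
    ancestral_mafs: tuple[float, ...]
    causal_effects: tuple[float, ...] = ()
    ld_rho: float = 0.0
    private_snps: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.snp_names) != len(set(self.snp_names)):
            raise ValueError(f"duplicate SNP names in gene {self.gene_name}")
        if len(self.ancestral_mafs) != len(self.snp_names):
            raise ValueError("ancestral_mafs must align with snp_names")
        for p in self.ancestral_mafs:
            if not (math.isfinite(p) and 0.0 < p <= 0.5):
                raise ValueError(f"ancestral MAF must be in (0, 0.5], got {p}")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        if not self.causal_effects:
            object.__setattr__(self, "causal_effects", (0.0,) * len(self.snp_names))
        if len(self.causal_effects) != len(self.snp_names):
            raise ValueError("causal_effects must align with snp_names")
        unknown = set(self.private_snps) - set(self.snp_names)
        if unknown:
            raise ValueError(f"private_snps not in gene: {sorted(unknown)}")

    @property
    def is_causal(self) -> bool:
        return any(e != 0.0 for e in self.causal_effects)


@dataclass(frozen=True)
class TraitModel:
    """Additive generating model for the quantitative trait Q1."""

    intercept: float = 0.0
    age_effect: float = 0.0
    sex_effect: float = 0.0
    smoke_effect: float = 0.0
    residual_sd: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.residual_sd) and self.residual_sd > 0):
            raise ValueError(f"residual_sd must be > 0, got {self.residual_sd}")


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs minor-allele counts with the SNP -> gene map."""

    values: np.ndarray  # (n, p) int8, entries in {0, 1, 2}
    individual_ids: list[str]
    snp_ids: list[str]
    gene_of_snp: dict[str, str]
    populations: np.ndarray | None = None  # per-individual population index

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n, p = self.values.shape
        if len(self.individual_ids) != n or len(self.snp_ids) != p:
            raise ValueError("id lengths do not match matrix shape")
        if len(set(self.snp_ids)) != p:
            raise ValueError("snp_ids must be unique")
        if not np.isin(self.values, (0, 1, 2)).all():
            raise ValueError("genotype entries must be in {0, 1, 2}")
        missing = [s for s in self.snp_ids if s not in self.gene_of_snp]
        if missing:
            raise ValueError(f"SNPs without a gene mapping: {missing[:5]}")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def column(self, snp_id: str) -> np.ndarray:
        return self.values[:, self.snp_ids.index(snp_id)]

    def mafs(self) -> pd.Series:
        f = self.values.mean(axis=0) / 2.0
        return pd.Series(np.minimum(f, 1.0 - f), index=self.snp_ids, name="maf")

    def snps_of_gene(self, gene: str) -> list[str]:
        return [s for s in self.snp_ids if self.gene_of_snp[s] == gene]

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.snp_ids:
            seen.setdefault(self.gene_of_snp[s], None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.individual_ids, columns=self.snp_ids)


@dataclass
class ReplicateSet:
    """A fixed genotype matrix with one phenotype table per replicate.

    ``truth`` records the generating architecture (causal genes/SNPs and
    their effect sizes) so downstream confusion counts and bias reports
    can be scored against it.
    """

    genotypes: GenotypeMatrix
    phenotypes: list[pd.DataFrame]
    truth: dict

    @property
    def n_replicates(self) -> int:
        return len(self.phenotypes)


def draw_population_freqs(
    config: PopulationConfig, ancestral_maf: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw one allele frequency per population under Balding-Nichols.

    With ``differentiation = 0`` every population gets exactly the
    ancestral frequency.
    """
    if not (math.isfinite(ancestral_maf) and 0.0 < ancestral_maf <= 0.5):
        raise ValueError(f"ancestral_maf must be in (0, 0.5], got {ancestral_maf}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    k = config.n_populations
    f = config.differentiation
    if f == 0.0:
        return np.full(k, ancestral_maf)
    a = ancestral_maf * (1.0 - f) / f
    b = (1.0 - ancestral_maf) * (1.0 - f) / f
    return rng.beta(a, b, size=k)


def _gene_alleles(
    rng: np.random.Generator, n: int, freqs: np.ndarray, ld_rho: float
) -> np.ndarray:
    """Two correlated allele draws per individual for one gene.

    Returns an (n, n_snps) genotype block. Each allele indicator is
    Bernoulli(freq) marginally; within one allele draw, indicators share
    a gene-level Gaussian factor with loading sqrt(ld_rho).
    """
    n_snps = freqs.shape[0]
    thresholds = _norm_ppf(freqs)  # allele present iff z < threshold
    geno = np.zeros((n, n_snps), dtype=np.int8)
    for _ in range(2):  # two independent allele draws -> HWE
        if ld_rho > 0.0:
            shared = rng.standard_normal((n, 1))
            z = math.sqrt(ld_rho) * shared + math.sqrt(1.0 - ld_rho) * rng.standard_normal(
                (n, n_snps)
            )
        else:
            z = rng.standard_normal((n, n_snps))
        geno += (z < thresholds[None, :]).astype(np.int8)
    return geno


def _norm_ppf(p: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    out = np.full(p.shape, -np.inf)
    pos = p > 0.0
    out[pos] = norm.ppf(p[pos])
    return out


def simulate_genotypes(
    pop_config: PopulationConfig,
    gene_configs: list[GeneConfig],
    seed: int,
) -> GenotypeMatrix:
    """Simulate the fixed genotype matrix for a study.

    Per SNP, population frequencies come from Balding-Nichols; per
    individual, genotypes are Binomial(2, pop frequency) (HWE), with
    optional within-gene copula LD. Deterministic for a fixed seed.
    """
    all_snps = [s for g in gene_configs for s in g.snp_names]
    if len(all_snps) != len(set(all_snps)):
        raise ValueError("duplicate SNP names across genes")
    rng = np.random.default_rng(seed)
    n = pop_config.n_individuals
    pop_labels = np.repeat(np.arange(pop_config.n_populations), pop_config.sizes)

    blocks: list[np.ndarray] = []
    gene_of_snp: dict[str, str] = {}
    for gene in gene_configs:
        mafs = np.asarray(gene.ancestral_mafs)
        # population-specific frequencies, one row per population; SNPs of
        # a gene with LD differentiate together (comonotone beta quantiles),
        # emulating drift acting on a shared haplotype background
        f = pop_config.differentiation
        if gene.ld_rho > 0.0 and f > 0.0:
            from scipy.stats import beta as beta_dist

            u = rng.uniform(size=pop_config.n_populations)
            freqs = np.column_stack(
                [beta_dist.ppf(u, p * (1 - f) / f, (1 - p) * (1 - f) / f) for p in mafs]
            )
        else:
            freqs = np.vstack(
                [draw_population_freqs(pop_config, p, rng) for p in mafs]
            ).T  # (n_pops, n_snps)
        block = np.zeros((n, len(gene.snp_names)), dtype=np.int8)
        for k, size in enumerate(pop_config.sizes):
            rows = pop_labels == k
            block[rows] = _gene_alleles(rng, int(size), freqs[k], gene.ld_rho)
        for j, snp in enumerate(gene.snp_names):
            gene_of_snp[snp] = gene.gene_name
            if snp in gene.private_snps:
                block[:, j] = 0
                block[rng.integers(0, n), j] = 1  # one singleton heterozygote
        blocks.append(block)

    values = np.hstack(blocks) if blocks else np.zeros((n, 0), dtype=np.int8)
    ids = [f"IND{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(values, ids, all_snps, gene_of_snp, populations=pop_labels)


def simulate_covariates(
    genotypes: GenotypeMatrix, seed: int, age_range: tuple[float, float] = (20.0, 70.0)
) -> pd.DataFrame:
    """Covariates fixed across replicates: Age ~ U(range), Sex/Smoke ~ Bernoulli(0.5)."""
    rng = np.random.default_rng(seed)
    n = genotypes.n_individuals
    pops = (
        genotypes.populations
        if genotypes.populations is not None
        else np.zeros(n, dtype=int)
    )
    return pd.DataFrame(
        {
            "IID": genotypes.individual_ids,
            "Age": np.round(rng.uniform(*age_range, size=n), 1),
            "Sex": rng.integers(0, 2, size=n),
            "Smoke": rng.integers(0, 2, size=n),
            "Pop": pops,
        }
    )


def simulate_replicates(
    genotypes: GenotypeMatrix,
    trait_model: TraitModel,
    gene_configs: list[GeneConfig],
    n_replicates: int,
    seed: int,
) -> ReplicateSet:
    """Redraw the trait ``n_replicates`` times over one fixed genotype matrix.

    Q1 = intercept + sum(effect x minor-allele count) + covariate terms
    + Normal(0, residual_sd) noise; the noise is the only quantity that
    changes between replicates.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    effects = {}
    for g in gene_configs:
        for snp, beta in zip(g.snp_names, g.causal_effects):
            if beta != 0.0:
                effects[snp] = beta
    unknown = set(effects) - set(genotypes.snp_ids)
    if unknown:
        raise ValueError(f"causal SNPs absent from genotypes: {sorted(unknown)}")

    covariates = simulate_covariates(genotypes, seed)
    genetic = np.zeros(genotypes.n_individuals)
    for snp, beta in effects.items():
        genetic += beta * genotypes.column(snp)
    base = (
        trait_model.intercept
        + genetic
        + trait_model.age_effect * covariates["Age"].to_numpy()
        + trait_model.sex_effect * covariates["Sex"].to_numpy()
        + trait_model.smoke_effect * covariates["Smoke"].to_numpy()
    )

    rng = np.random.default_rng(seed + 1)
    phenotypes = []
    for _ in range(n_replicates):
        q1 = base + rng.normal(0.0, trait_model.residual_sd, size=base.shape[0])
        tab = covariates.copy()
        tab.insert(1, "Q1", q1)
        phenotypes.append(tab[PHENOTYPE_COLUMNS])

    causal_genes = sorted({g.gene_name for g in gene_configs if g.is_causal})
    truth = {
        "causal_genes": causal_genes,
        "causal_snps": sorted(effects),
        "snp_effects": dict(sorted(effects.items())),
        "trait_model": trait_model,
        "seed": seed,
    }
    return ReplicateSet(genotypes, phenotypes, truth)
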