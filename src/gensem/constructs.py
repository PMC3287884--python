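"""Helpers for turning screened SNPs into parsimonious latent gene
constructs: reliability, LD, eigenvalue screens, a deterministic greedy
SNP selector, and assembly of full model-spec text.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sem.spec import parse_model_spec
from .simulate import GenotypeMatrix

__all__ = [
    "ConstructConfig",
    "ConstructReport",
    "cronbach_alpha",
    "cronbach_alpha_from_cov",
    "ld_r2",
    "ld_r2_table",
    "eigen_screen",
    "select_snps",
    "construct_report",
    "assemble_model",
]


@dataclass(frozen=True)
class ConstructConfig:
    """Greedy-selection thresholds: keep at most ``max_indicators`` SNPs
    per gene, pruning any SNP whose max LD r2 with already-kept SNPs
    exceeds ``r2_threshold``."""

    max_indicators: int = 6
    r2_threshold: float = 0.8


@dataclass
class ConstructReport:
    gene: str
    selected_snps: list[str]
    eigenvalues: np.ndarray
    cronbach_alpha: float
    ld_r2: pd.DataFrame

    def to_text(self) -> str:
        lines = [f"gene\t{self.gene}",
                 "selected\t" + ",".join(self.selected_snps),
                 "eigenvalues\t" + "\t".join(f"{v:.4f}" for v in self.eigenvalues),
                 f"cronbach_alpha\t{self.cronbach_alpha:.4f}", "ld_r2"]
        lines.append(self.ld_r2.to_csv(sep="\t", float_format="%.4f").rstrip())
        return "\n".join(lines) + "\n"


def cronbach_alpha_from_cov(cov: np.ndarray) -> float:
    cov = np.asarray(cov, dtype=float)
    k = cov.shape[0]
    if k < 2:
        raise ValueError("need >= 2 items")
    total = float(cov.sum())
    if total <= 0:
        raise ValueError("zero total variance")
    return (k / (k - 1)) * (1.0 - float(np.trace(cov)) / total)


def cronbach_alpha(item_matrix: np.ndarray) -> float:
    """(k/(k-1)) (1 - sum of item variances / variance of the item sum)."""
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need an n x k matrix with k >= 2 items")
    if X.shape[0] < 3:
        raise ValueError("need n >= 3 observations")
    return cronbach_alpha_from_cov(np.cov(X, rowvar=False, ddof=1))


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Composite LD: squared Pearson correlation of additive codes."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("genotype vectors must have equal length")
    if np.var(g1) == 0 or np.var(g2) == 0:
        raise ValueError("monomorphic input")
    r = np.corrcoef(g1, g2)[0, 1]
    return float(r * r)


def ld_r2_table(genotypes: GenotypeMatrix, snps: list[str]) -> pd.DataFrame:
    cols = {s: genotypes.column(s).astype(float) for s in snps}
    poly = [s for s in snps if np.var(cols[s]) > 0]
    dropped = set(snps) - set(poly)
    if dropped:
        warnings.warn(f"monomorphic SNPs dropped from LD table: {sorted(dropped)}")
    X = np.column_stack([cols[s] for s in poly])
    R = np.corrcoef(X, rowvar=False) if len(poly) > 1 else np.ones((len(poly), len(poly)))
    return pd.DataFrame(R ** 2, index=poly, columns=poly)


def eigen_screen(snp_matrix: np.ndarray) -> np.ndarray:
    """Non-increasing eigenvalues of the SNP correlation matrix.

    Monomorphic columns are dropped with a warning; the eigenvalues sum
    to the number of polymorphic SNPs.
    """
    X = np.asarray(snp_matrix, dtype=float)
    variances = X.var(axis=0)
    if (variances == 0).any():
        warnings.warn(f"{int((variances == 0).sum())} monomorphic column(s) dropped")
        X = X[:, variances > 0]
    if X.shape[1] < 2:
        raise ValueError("need >= 2 polymorphic SNPs")
    R = np.corrcoef(X, rowvar=False)
    vals = np.linalg.eigvalsh(R)[::-1]
    return np.clip(vals, 0.0, None)


def select_snps(
    gene: str,
    assoc_results: pd.DataFrame,
    ld_table: pd.DataFrame,
    config: ConstructConfig = ConstructConfig(),
) -> list[str]:
    """Deterministic greedy SNP selection for one gene construct.

    Rank the gene's tested SNPs by stage-1 p-value (ties by SNP id),
    then keep a SNP only if its max r2 with every already-kept SNP is at
    most the threshold, stopping at ``max_indicators``.
    """
    sub = assoc_results[(assoc_results["gene"] == gene)]
    sub = sub[~sub["snp_id"].str.endswith("__rare")]
    if sub.empty:
        raise ValueError(f"no stage-1 results for gene {gene}")
    ranked = sub.sort_values(["p", "snp_id"], kind="mergesort")["snp_id"].tolist()
    kept: list[str] = []
    for snp in ranked:
        if len(kept) >= config.max_indicators:
            break
        if snp not in ld_table.index:
            continue
        if all(ld_table.loc[snp, k] <= config.r2_threshold for k in kept):
            kept.append(snp)
    return kept


def construct_report(
    gene: str, genotypes: GenotypeMatrix, selected_snps: list[str]
) -> ConstructReport:
    X = np.column_stack([genotypes.column(s).astype(float) for s in selected_snps])
    table = ld_r2_table(genotypes, selected_snps)
    alpha = cronbach_alpha(X) if X.shape[1] >= 2 else float("nan")
    eig = eigen_screen(X) if X.shape[1] >= 2 else np.array([1.0])
    return ConstructReport(gene, list(selected_snps), eig, alpha, table)


def assemble_model(
    gene_constructs: dict[str, list[str]],
    trait: str = "Q1",
    covariates: tuple[str, ...] = (),
    popstr_vars: tuple[str, ...] = (),
    inter_gene_paths: list[tuple[str, str]] | None = None,
) -> str:
    """Emit full model-spec text: one latent per gene over its selected
    SNPs, optional PopStr latent over the population indicator + PCs
    (marker loading on the first listed variable), paths gene -> trait,
    PopStr -> genes and trait, covariate -> trait, and any user-declared
    gene -> gene paths.  The output always parses and is identified.
    """
    if not gene_constructs:
        raise ValueError("need at least one gene construct")
    snps = [s for v in gene_constructs.values() for s in v]
    collision = (set(snps) | {trait}) & (set(covariates) | set(popstr_vars))
    if collision:
        raise ValueError(f"name collision between indicators and covariates: {sorted(collision)}")
    lines = []
    for gene, inds in gene_constructs.items():
        if not inds:
            raise ValueError(f"gene {gene} has no selected SNPs")
        lines.append(f"latent {gene} = " + " + ".join(inds))
    if popstr_vars:
        lines.append("latent PopStr = " + " + ".join(popstr_vars))
    for gene in gene_constructs:
        lines.append(f"path {gene} -> {trait}")
    if popstr_vars:
        for gene in gene_constructs:
            lines.append(f"path PopStr -> {gene}")
        lines.append(f"path PopStr -> {trait}")
    for cov in covariates:
        lines.append(f"path {cov} -> {trait}")
    for src, dst in inter_gene_paths or []:
        for g in (src, dst):
            if g not in gene_constructs:
                raise ValueError(f"inter-gene path names unknown gene {g!r}")
        lines.append(f"path {src} -> {dst}")
    text = "\n".join(lines) + "\n"
    parse_model_spec(text)  # guarantee the emitted spec is valid
    return text
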