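"""Stage-1 genome screen: per-SNP additive regressions with covariate and
principal-component adjustment, rare-variant collapsing, Bonferroni-based
selection of potentially interesting genes (PIGs), and confusion counts
against a known causal-gene list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import PCA

from .simulate import GenotypeMatrix

__all__ = [
    "AssocResult",
    "ScreenConfig",
    "ScreenDesign",
    "ConfusionCounts",
    "compute_maf",
    "pca_genotypes",
    "ols_regression",
    "collapse_rare",
    "bonferroni_threshold",
    "scan",
    "identify_pigs",
    "confusion_counts",
]


@dataclass(frozen=True)
class AssocResult:
    """One tested column under one covariate model."""

    snp_id: str
    beta: float
    se: float
    p_value: float
    model_tag: str
    degenerate: bool = False  # zero residual variance: beta exact, p meaningless


@dataclass(frozen=True)
class ScreenConfig:
    """Stage-1 configuration.

    ``covariate_sets`` maps a model tag to phenotype-table column names;
    the token ``PC`` expands to the first ``n_pcs`` genotype principal
    components.  ``collapse_coding`` selects the gene-level rare-variant
    summary: ``indicator`` (carrier of >= 1 rare minor allele) or
    ``count`` (total rare minor alleles).
    """

    rare_maf_threshold: float = 0.05
    alpha: float = 0.05
    n_pcs: int = 0
    collapse: bool = True
    collapse_coding: str = "indicator"
    covariate_sets: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"adjusted": ("Age", "Sex", "Smoke", "PC")}
    )

    def __post_init__(self) -> None:
        if not (0.0 < self.rare_maf_threshold < 0.5):
            raise ValueError("rare_maf_threshold must be in (0, 0.5)")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.collapse_coding not in ("indicator", "count"):
            raise ValueError("collapse_coding must be 'indicator' or 'count'")


@dataclass
class ScreenDesign:
    """Columns actually tested: common SNPs plus per-gene collapsed columns."""

    columns: np.ndarray  # (n, t)
    column_ids: list[str]
    gene_of_column: dict[str, str]
    collapsed: dict[str, list[str]]  # collapsed column id -> rare SNPs it summarises

    @property
    def n_tests(self) -> int:
        return len(self.column_ids)


@dataclass
class ConfusionCounts:
    """Gene-level TP/FP/FN per replicate with mean/SD/range summaries."""

    per_replicate: pd.DataFrame  # columns TP, FP, FN, one row per replicate

    def summary(self) -> pd.DataFrame:
        df = self.per_replicate
        return pd.DataFrame(
            {
                "mean": df.mean(),
                "sd": df.std(ddof=1) if len(df) > 1 else df.std(ddof=0),
                "min": df.min(),
                "max": df.max(),
            }
        ).T


def compute_maf(genotype_column: np.ndarray) -> float:
    """Minor-allele frequency of an additive 0/1/2 column: min(f, 1 - f)."""
    col = np.asarray(genotype_column)
    if col.size == 0:
        raise ValueError("empty genotype column")
    if not np.isin(col, (0, 1, 2)).all():
        raise ValueError("genotype entries must be in {0, 1, 2}")
    f = col.mean() / 2.0
    return float(min(f, 1.0 - f))


def pca_genotypes(genotypes: GenotypeMatrix | np.ndarray, k: int) -> np.ndarray:
    """Top-k principal-component scores of the column-centered genotype matrix.

    Columns are ordered by decreasing eigenvalue; each score column is
    sign-fixed so its largest-magnitude entry is positive.
    """
    X = genotypes.values if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes)
    X = X.astype(float)
    n, p = X.shape
    if not 1 <= k < min(n, p):
        raise ValueError(f"k must satisfy 1 <= k < min(n, p) = {min(n, p)}")
    scores = PCA(n_components=k, svd_solver="full").fit_transform(X)
    for j in range(k):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] *= -1.0
    return scores


def ols_regression(
    y: np.ndarray,
    predictor: np.ndarray,
    covariates: np.ndarray | None = None,
    snp_id: str = "g",
    model_tag: str = "crude",
) -> AssocResult:
    """Additive linear regression of the trait on one genotype column.

    Returns the predictor's coefficient, its standard error, and the
    two-sided p-value from the t reference distribution with n - k
    degrees of freedom.  A rank-deficient design raises, naming the
    collinear columns; an exact fit is returned flagged degenerate.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(predictor, dtype=float)
    parts = [np.ones_like(g), g]
    names = ["const", snp_id]
    if covariates is not None and np.size(covariates):
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != y.shape[0]:
            C = C.T
        parts.extend(C.T)
        names.extend(f"cov{j}" for j in range(C.shape[1]))
    X = np.column_stack(parts)
    n, ncoef = X.shape
    if n <= ncoef:
        raise ValueError(f"n = {n} too small for {ncoef} coefficients")
    rank = np.linalg.matrix_rank(X)
    if rank < ncoef:
        # locate offending columns by greedy rank growth
        bad, kept = [], np.ones((n, 0))
        for j in range(ncoef):
            cand = np.column_stack([kept, X[:, j]])
            if np.linalg.matrix_rank(cand) > kept.shape[1]:
                kept = cand
            else:
                bad.append(names[j])
        raise ValueError(f"design matrix rank-deficient; collinear columns: {bad}")
    fit = sm.OLS(y, X).fit()
    resid_var = float(fit.ssr / fit.df_resid) if fit.df_resid > 0 else 0.0
    degenerate = resid_var < 1e-12 * max(1.0, float(np.var(y)))
    return AssocResult(
        snp_id=snp_id,
        beta=float(fit.params[1]),
        se=float(fit.bse[1]) if not degenerate else 0.0,
        p_value=float(fit.pvalues[1]) if not degenerate else 0.0,
        model_tag=model_tag,
        degenerate=degenerate,
    )


def collapse_rare(
    genotypes: GenotypeMatrix,
    rare_maf_threshold: float = 0.05,
    coding: str = "indicator",
) -> ScreenDesign:
    """Replace each gene's rare SNPs (MAF < threshold) with one column.

    ``indicator`` coding sets the column to 1 for carriers of at least
    one minor allele at any rare SNP of the gene (equal weighting);
    ``count`` coding sums the rare minor alleles.  Common SNPs pass
    through unchanged; a gene with no rare SNPs contributes no collapsed
    column.
    """
    mafs = genotypes.mafs()
    rare = mafs.index[mafs < rare_maf_threshold]
    cols, ids, gene_of, collapsed = [], [], {}, {}
    for snp in genotypes.snp_ids:
        if snp not in rare:
            cols.append(genotypes.column(snp).astype(float))
            ids.append(snp)
            gene_of[snp] = genotypes.gene_of_snp[snp]
    for gene in genotypes.genes:
        rare_snps = [s for s in genotypes.snps_of_gene(gene) if s in set(rare)]
        if not rare_snps:
            continue
        block = np.column_stack([genotypes.column(s) for s in rare_snps])
        total = block.sum(axis=1).astype(float)
        col = (total > 0).astype(float) if coding == "indicator" else total
        cid = f"{gene}__rare"
        cols.append(col)
        ids.append(cid)
        gene_of[cid] = gene
        collapsed[cid] = rare_snps
    columns = np.column_stack(cols) if cols else np.zeros((genotypes.n_individuals, 0))
    return ScreenDesign(columns, ids, gene_of, collapsed)


def full_design(genotypes: GenotypeMatrix) -> ScreenDesign:
    """All SNPs tested individually (no collapsing)."""
    return ScreenDesign(
        genotypes.values.astype(float),
        list(genotypes.snp_ids),
        dict(genotypes.gene_of_snp),
        {},
    )


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    return alpha / n_tests


def _covariate_matrix(
    phenotypes: pd.DataFrame, columns: tuple[str, ...], pcs: np.ndarray | None
) -> np.ndarray | None:
    parts = []
    for c in columns:
        if c == "PC":
            if pcs is None:
                raise ValueError("covariate set requests PCs but n_pcs = 0")
            parts.append(pcs)
        else:
            if c not in phenotypes:
                raise ValueError(f"phenotype table lacks covariate column {c!r}")
            parts.append(phenotypes[c].to_numpy(dtype=float)[:, None])
    return np.hstack(parts) if parts else None


def scan(
    design: ScreenDesign | GenotypeMatrix,
    phenotypes: pd.DataFrame,
    config: ScreenConfig,
    pcs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Run every covariate model over every tested column.

    Returns a tidy table (model_tag, snp_id, gene, beta, se, p), sorted
    by (model_tag, snp_id). Individual ids must align between genotype
    rows and the phenotype table.
    """
    if isinstance(design, GenotypeMatrix):
        ids = design.individual_ids
        design = (
            collapse_rare(design, config.rare_maf_threshold, config.collapse_coding)
            if config.collapse
            else full_design(design)
        )
    else:
        ids = None
    if ids is not None:
        pheno_ids = [str(i) for i in phenotypes["IID"]]
        if pheno_ids != list(ids):
            offending = [a for a, b in zip(pheno_ids, ids) if a != b][:5]
            raise ValueError(f"genotype/phenotype id mismatch, e.g. {offending}")
    y = phenotypes["Q1"].to_numpy(dtype=float)
    rows = []
    for tag in sorted(config.covariate_sets):
        cov = _covariate_matrix(phenotypes, config.covariate_sets[tag], pcs)
        for j, cid in enumerate(design.column_ids):
            col = design.columns[:, j]
            if np.var(col) == 0.0:
                continue  # monomorphic under this sample: untestable
            res = ols_regression(y, col, cov, snp_id=cid, model_tag=tag)
            rows.append(
                {
                    "model_tag": tag,
                    "snp_id": cid,
                    "gene": design.gene_of_column[cid],
                    "beta": res.beta,
                    "se": res.se,
                    "p": res.p_value,
                }
            )
    out = pd.DataFrame(rows, columns=["model_tag", "snp_id", "gene", "beta", "se", "p"])
    return out.sort_values(["model_tag", "snp_id"], kind="mergesort").reset_index(drop=True)


def identify_pigs(
    results: pd.DataFrame, threshold: float, model_tag: str | None = None
) -> set[str]:
    """Genes with at least one tested column at p <= threshold."""
    df = results
    if model_tag is not None:
        df = df[df["model_tag"] == model_tag]
    return set(df.loc[df["p"] <= threshold, "gene"])


def confusion_counts(
    pigs_per_replicate: list[set[str]], causal_genes: set[str] | list[str]
) -> ConfusionCounts:
    """TP/FP/FN gene counts per replicate against the causal list."""
    causal = set(causal_genes)
    if not causal:
        raise ValueError("causal gene list must be non-empty")
    rows = [
        {
            "TP": len(pigs & causal),
            "FP": len(pigs - causal),
            "FN": len(causal - pigs),
        }
        for pigs in pigs_per_replicate
    ]
    return ConfusionCounts(pd.DataFrame(rows))
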