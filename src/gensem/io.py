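"""Text I/O: PLINK-style .ped/.map, additive matrix export, phenotype tables.

The .ped carries two allele columns per SNP; the minor allele is always
written as ``A`` and the major as ``G``, so additive recoding on read
(count of ``A``) reproduces the original 0/1/2 matrix exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import (
    PHENOTYPE_COLUMNS,
    GeneConfig,
    GenotypeMatrix,
    PopulationConfig,
    ReplicateSet,
    TraitModel,
)

_MINOR, _MAJOR = "A", "G"


def write_ped_map(genotypes: GenotypeMatrix, prefix: str | Path) -> tuple[Path, Path]:
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    try:
        with map_path.open("w") as fh:
            for pos, snp in enumerate(genotypes.snp_ids, start=1):
                fh.write(f"1\t{snp}\t0\t{pos}\n")
        allele_pairs = {0: f"{_MAJOR} {_MAJOR}", 1: f"{_MINOR} {_MAJOR}", 2: f"{_MINOR} {_MINOR}"}
        with ped_path.open("w") as fh:
            for i, iid in enumerate(genotypes.individual_ids):
                geno = " ".join(allele_pairs[int(v)] for v in genotypes.values[i])
                fh.write(f"FAM{i + 1} {iid} 0 0 0 -9 {geno}\n")
    except OSError as exc:
        raise OSError(f"failed writing PLINK files at {prefix}: {exc}") from exc
    return ped_path, map_path


def read_ped_map(prefix: str | Path, gene_of_snp: dict[str, str] | None = None) -> GenotypeMatrix:
    prefix = Path(prefix)
    ped_path, map_path = prefix.with_suffix(".ped"), prefix.with_suffix(".map")
    snp_ids = []
    with map_path.open() as fh:
        for line in fh:
            parts = line.split()
            if parts:
                snp_ids.append(parts[1])
    iids, rows = [], []
    with ped_path.open() as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            iids.append(parts[1])
            alleles = parts[6:]
            if len(alleles) != 2 * len(snp_ids):
                raise ValueError(
                    f"{ped_path}: expected {2 * len(snp_ids)} allele fields, got {len(alleles)}"
                )
            counts = [
                (alleles[2 * j] == _MINOR) + (alleles[2 * j + 1] == _MINOR)
                for j in range(len(snp_ids))
            ]
            rows.append(counts)
    mapping = gene_of_snp if gene_of_snp is not None else {s: s for s in snp_ids}
    return GenotypeMatrix(np.array(rows, dtype=np.int8), iids, snp_ids, mapping)


def write_genotype_matrix(genotypes: GenotypeMatrix, path: str | Path) -> Path:
    """Additive-coded matrix: tab-delimited, header of SNP ids, IID first column."""
    path = Path(path)
    genotypes.to_frame().rename_axis("IID").to_csv(path, sep="\t")
    return path


def read_genotype_matrix(path: str | Path, gene_of_snp: dict[str, str] | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    mapping = gene_of_snp if gene_of_snp is not None else {s: s for s in df.columns}
    return GenotypeMatrix(
        df.to_numpy(dtype=np.int8), [str(i) for i in df.index], list(df.columns), mapping
    )


def write_gene_map(gene_of_snp: dict[str, str], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("snp\tgene\n")
        for snp, gene in gene_of_snp.items():
            fh.write(f"{snp}\t{gene}\n")
    return path


def read_gene_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["snp"], df["gene"]))


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing phenotype columns {missing}")
    return df


def write_study(replicate_set: ReplicateSet, directory: str | Path) -> dict[str, list[Path]]:
    """Write a full study: .ped/.map, additive matrix, gene map, per-replicate phenotypes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    geno = replicate_set.genotypes
    ped, mp = write_ped_map(geno, directory / "study")
    mat = write_genotype_matrix(geno, directory / "genotypes.tsv")
    gmap = write_gene_map(geno.gene_of_snp, directory / "gene_map.tsv")
    pheno_paths = []
    for r, tab in enumerate(replicate_set.phenotypes, start=1):
        pheno_paths.append(write_phenotypes(tab, directory / f"phenotypes_rep{r:03d}.tsv"))
    truth = {
        k: v for k, v in replicate_set.truth.items() if k in ("causal_genes", "causal_snps", "snp_effects", "seed")
    }
    (directory / "truth.json").write_text(json.dumps(truth, indent=1))
    return {"ped": [ped], "map": [mp], "matrix": [mat], "gene_map": [gmap], "phenotypes": pheno_paths}


def read_study(directory: str | Path) -> ReplicateSet:
    directory = Path(directory)
    gene_of_snp = read_gene_map(directory / "gene_map.tsv")
    geno = read_ped_map(directory / "study", gene_of_snp)
    phenos = [read_phenotypes(p) for p in sorted(directory.glob("phenotypes_rep*.tsv"))]
    truth_file = directory / "truth.json"
    truth = json.loads(truth_file.read_text()) if truth_file.exists() else {}
    if phenos and "Pop" in phenos[0]:
        geno.populations = phenos[0]["Pop"].to_numpy()
    return ReplicateSet(geno, phenos, truth)


def load_study_config(path: str | Path) -> dict:
    """Parse a YAML study config into generator objects.

    Top-level keys: ``seed`` (mandatory), ``populations`` (sizes,
    differentiation), ``genes`` (list of GeneConfig fields), ``trait``
    (TraitModel fields), ``n_replicates``.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if "seed" not in raw:
        raise ValueError(f"{path}: study config requires a top-level 'seed'")
    pops = raw.get("populations", {})
    pop_config = PopulationConfig(
        sizes=tuple(pops.get("sizes", PopulationConfig().sizes)),
        differentiation=float(pops.get("differentiation", PopulationConfig().differentiation)),
    )
    genes = [
        GeneConfig(
            gene_name=g["gene_name"],
            snp_names=tuple(g["snp_names"]),
            ancestral_mafs=tuple(g["ancestral_mafs"]),
            causal_effects=tuple(g.get("causal_effects", ())),
            ld_rho=float(g.get("ld_rho", 0.0)),
            private_snps=tuple(g.get("private_snps", ())),
        )
        for g in raw.get("genes", [])
    ]
    trait = TraitModel(**raw.get("trait", {}))
    return {
        "seed": int(raw["seed"]),
        "pop_config": pop_config,
        "gene_configs": genes,
        "trait_model": trait,
        "n_replicates": int(raw.get("n_replicates", 1)),
    }
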