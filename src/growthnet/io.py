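"""Readers and writers for the external formats the pipeline touches.

Formats: PLINK-text ``.ped``/``.map`` genotypes, TSV pedigree /
phenotype / gene-annotation tables (BED accepted for annotation, with
0-based half-open coordinates converted on read), Cytoscape SIF and
edge/node TSV network exports.  All writers emit deterministically
sorted output; coordinates are 1-based inclusive in memory.
"""
from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    CoassociationNetwork,
    GeneAnnotationSet,
    GenotypeMatrix,
    GwasTable,
    Pedigree,
    SnpMap,
    TraitTable,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PLINK text genotypes


def write_genotypes(genotypes: GenotypeMatrix, path_ped, path_map, snp_map: SnpMap,
                    pedigree: Pedigree | None = None) -> None:
    """PLINK-text output; the counted (minor) allele is written as ``A``.

    Writing the minor allele as the alphabetically first label makes
    write-then-read an identity even for SNPs at frequency exactly 0.5
    (the reader breaks frequency ties alphabetically).
    """
    order = [s for s in snp_map.snps if s in set(genotypes.snps)]
    vals = genotypes.values[order]
    parents = {}
    if pedigree is not None:
        parents = {
            r["animal"]: (r["sire"], r["dam"]) for _, r in pedigree.table.iterrows()
        }
    code = {-1.0: "B B", 0.0: "A B", 1.0: "A A"}
    with open(path_ped, "w") as fh:
        for animal, row in vals.iterrows():
            sire, dam = parents.get(animal, ("0", "0"))
            cells = [code.get(v, "0 0") if v == v else "0 0" for v in row]
            fh.write(f"{animal} {animal} {sire} {dam} 0 -9 " + " ".join(cells) + "\n")
    mt = snp_map.table.set_index("snp").loc[order].reset_index()
    with open(path_map, "w") as fh:
        for _, r in mt.iterrows():
            cm = 0.0 if pd.isna(r["cm"]) else float(r["cm"])
            fh.write(f"{r['chrom']}\t{r['snp']}\t{cm:g}\t{int(r['pos'])}\n")


def read_genotypes(path_ped, path_map) -> tuple[GenotypeMatrix, SnpMap]:
    """Read PLINK text; recode to minor-allele count - 1, ``0 0`` = missing."""
    map_rows = []
    with open(path_map) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ValueError(f"{path_map}:{ln}: expected 4 columns, got {len(parts)}")
            chrom, snp, cm, pos = parts
            map_rows.append((snp, chrom, int(pos), float(cm)))
    snp_map = SnpMap(pd.DataFrame(map_rows, columns=["snp", "chrom", "pos", "cm"]))
    n_snps = len(snp_map)

    animals: list[str] = []
    allele_rows: list[list[str]] = []
    with open(path_ped) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{path_ped}:{ln}: expected {6 + 2 * n_snps} fields, got {len(parts)}"
                )
            animals.append(parts[1])
            allele_rows.append(parts[6:])
    alleles = np.array(allele_rows, dtype=object).reshape(len(animals), n_snps, 2)

    values = np.full((len(animals), n_snps), np.nan)
    for j, snp in enumerate(snp_map.snps):
        col = alleles[:, j, :]
        observed = col[col != "0"]
        uniq = sorted(set(observed.tolist()))
        if len(uniq) > 2:
            raise ValueError(f"SNP {snp} has more than two alleles: {uniq}")
        if not uniq:
            continue  # all missing
        counts = {a: int((observed == a).sum()) for a in uniq}
        if len(uniq) == 1:
            minor = uniq[0]
        else:
            a, b = uniq  # tie -> alphabetically first counted
            minor = a if counts[a] <= counts[b] else b
        miss = (col == "0").any(axis=1)
        cnt = (col == minor).sum(axis=1).astype(float)
        cnt[miss] = np.nan
        values[:, j] = cnt - 1.0
    geno = GenotypeMatrix(pd.DataFrame(values, index=animals, columns=snp_map.snps))
    return geno, snp_map


# ---------------------------------------------------------------------------
# TSV tables


def write_pedigree(pedigree: Pedigree, path) -> None:
    pedigree.table[["animal", "sire", "dam"]].to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> Pedigree:
    tab = pd.read_csv(path, sep="\t", dtype=str)
    return Pedigree(tab)


def write_phenotypes(traits: TraitTable, path) -> None:
    out = pd.concat([traits.values, traits.covariates], axis=1)
    out.index.name = "animal"
    out.to_csv(path, sep="\t")


def read_phenotypes(path, roles: dict[str, str],
                    fixed_effects: dict[str, tuple[str, ...]] | None = None) -> TraitTable:
    """First column = animal id; columns named in ``roles`` are traits
    (numeric; unparseable cells become missing with a warning), the rest
    are categorical covariates."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    id_col = tab.columns[0]
    if tab[id_col].duplicated().any():
        dups = tab.loc[tab[id_col].duplicated(), id_col].tolist()
        raise ValueError(f"duplicate animal ids in phenotype file: {dups}")
    tab = tab.set_index(id_col)
    absent = [t for t in roles if t not in tab.columns]
    if absent:
        raise ValueError(f"roles reference absent traits: {absent}")
    trait_cols = [c for c in tab.columns if c in roles]
    values = tab[trait_cols].apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & tab[trait_cols].notna()
    if bad.to_numpy().any():
        log.warning("%d unparseable numeric phenotype cells set to missing",
                    int(bad.to_numpy().sum()))
    covariates = tab[[c for c in tab.columns if c not in roles]]
    return TraitTable(values, covariates, dict(roles), fixed_effects)


def write_annotation(genes: GeneAnnotationSet, path) -> None:
    genes.table.sort_values(["chrom", "start", "gene"]).to_csv(path, sep="\t", index=False)


def read_annotation(path) -> GeneAnnotationSet:
    """TSV (gene, chrom, start, end; 1-based inclusive) or BED
    (chrom, start, end, gene; 0-based half-open, converted on read)."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        tab = pd.read_csv(path, sep="\t", header=None, comment="#",
                          usecols=[0, 1, 2, 3],
                          names=["chrom", "start", "end", "gene"])
        tab["start"] = tab["start"].astype(np.int64) + 1  # to 1-based inclusive
        tab = tab[["gene", "chrom", "start", "end"]]
    else:
        tab = pd.read_csv(path, sep="\t")
    return GeneAnnotationSet(tab)


def write_gwas(gwas: GwasTable, path) -> None:
    long = gwas.effects.stack(future_stack=True).rename("effect").to_frame()
    long["lrt"] = (gwas.lrt if gwas.lrt is not None else gwas.effects * np.nan).stack(
        future_stack=True
    )
    long["p"] = gwas.pvalues.stack(future_stack=True)
    long.index.names = ["snp", "trait"]
    long.reset_index().sort_values(["snp", "trait"]).to_csv(path, sep="\t", index=False)


def read_gwas(path) -> GwasTable:
    long = pd.read_csv(path, sep="\t", dtype={"snp": str, "trait": str})
    effects = long.pivot(index="snp", columns="trait", values="effect")
    pvalues = long.pivot(index="snp", columns="trait", values="p")
    lrt = long.pivot(index="snp", columns="trait", values="lrt") if "lrt" in long else None
    return GwasTable(effects=effects, pvalues=pvalues, lrt=lrt)


# ---------------------------------------------------------------------------
# networks


def _sorted_edges(network: CoassociationNetwork):
    for u, v, data in network.graph.edges(data=True):
        a, b = sorted((u, v))
        yield a, b, float(data.get("r", np.nan))


def write_network_sif(network: CoassociationNetwork, path, relation: str = "pc") -> None:
    """One line per undirected edge, lexicographically smaller gene first."""
    lines = sorted(f"{a} {relation} {b}" for a, b, _ in _sorted_edges(network))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_network_edges(network: CoassociationNetwork, path) -> None:
    rows = sorted((a, b, r, abs(r)) for a, b, r in _sorted_edges(network))
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "correlation", "abs_correlation"]).to_csv(
        path, sep="\t", index=False
    )


def write_network_nodes(network: CoassociationNetwork, path) -> None:
    rows = sorted((g, d) for g, d in network.graph.degree)
    pd.DataFrame(rows, columns=["gene", "degree"]).to_csv(path, sep="\t", index=False)


def write_network(network: CoassociationNetwork, prefix, formats=("sif", "edge_tsv")) -> list[Path]:
    """Write a network under a path prefix; returns the files written."""
    prefix = Path(prefix)
    written = []
    if "sif" in formats:
        write_network_sif(network, prefix.with_suffix(".sif"))
        written.append(prefix.with_suffix(".sif"))
    if "edge_tsv" in formats:
        write_network_edges(network, prefix.with_suffix(".edges.tsv"))
        write_network_nodes(network, prefix.with_suffix(".nodes.tsv"))
        written += [prefix.with_suffix(".edges.tsv"), prefix.with_suffix(".nodes.tsv")]
    return written


def read_network(edge_tsv) -> CoassociationNetwork:
    tab = pd.read_csv(edge_tsv, sep="\t", dtype={"gene_a": str, "gene_b": str})
    g = nx.Graph()
    for _, row in tab.iterrows():
        g.add_edge(row["gene_a"], row["gene_b"], r=float(row["correlation"]))
    return CoassociationNetwork(g)
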