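"""Association weight matrix (AWM) assembly from a GWAS grid.

The AWM is a gene x trait matrix of column-standardized additive SNP
effects.  Rows enter through a selection cascade: SNPs associated with
any *key* trait at p <= 0.05; the average count A_P of *supportive*
traits those SNPs hit at p <= 0.05; all SNPs hitting at least A_P
supportive traits; a 2500-bp gene-proximity filter; and a
one-gene-one-SNP rule (most associated SNP, ties by lowest mean p).
Externally computed SNPs (e.g. causal variants absent from the chip)
can be injected and then behave exactly like chip SNPs.
"""
from __future__ import annotations

import logging
import operator
import warnings

import numpy as np
import pandas as pd

from .datatypes import AwmMatrix, GeneAnnotationSet, GwasTable, SnpMap, TraitTable

log = logging.getLogger(__name__)

_COMPARATORS = {">=": operator.ge, ">": operator.gt}


def standardize_effects(gwas: GwasTable) -> pd.DataFrame:
    """Column-wise z-scores of the effect grid (sample SD, n-1).

    Standardization runs over *all* SNPs in the grid, before any
    selection, so effects are comparable across traits.
    """
    eff = gwas.effects.astype(float)
    if len(eff) < 2:
        raise ValueError("need at least 2 SNPs to standardize effects")
    sd = eff.std(axis=0, ddof=1)
    zero = sd[(sd == 0) | sd.isna()].index.tolist()
    if zero:
        raise ValueError(f"zero-variance effect columns for traits: {zero}")
    return (eff - eff.mean(axis=0)) / sd


def significance_counts(gwas: GwasTable, traits: list[str], p_thresh: float = 0.05) -> pd.Series:
    """Per SNP, the number of listed traits associated at p <= threshold."""
    return (gwas.pvalues[traits] <= p_thresh).sum(axis=1)


def select_key_snps(gwas: GwasTable, key_traits: list[str], p_thresh: float = 0.05) -> set[str]:
    """SNPs associated with at least one key trait at p <= threshold."""
    if not key_traits:
        raise ValueError("at least one key trait required")
    hit = (gwas.pvalues[key_traits] <= p_thresh).any(axis=1)
    return set(gwas.pvalues.index[hit])


def compute_ap(
    gwas: GwasTable,
    s_key: set[str],
    supportive_traits: list[str],
    p_thresh: float = 0.05,
) -> float:
    """A_P: mean number of supportive traits hit by key-selected SNPs."""
    if not s_key:
        raise ValueError("no key-associated SNPs: cannot compute A_P")
    counts = significance_counts(gwas, supportive_traits, p_thresh).loc[sorted(s_key)]
    a_p = float(counts.mean())
    if a_p == 0:
        warnings.warn(
            "A_P is 0: supportive selection will admit every SNP", stacklevel=2
        )
    return a_p


def select_supportive_snps(
    gwas: GwasTable,
    a_p: float,
    supportive_traits: list[str],
    p_thresh: float = 0.05,
    comparator: str = ">=",
) -> set[str]:
    """Grid-wide SNPs whose supportive-trait hit count satisfies A_P.

    ``comparator`` is ``">="`` ("at least A_P") or ``">"`` ("more than
    A_P"); A_P is compared unrounded.
    """
    if a_p < 0:
        raise ValueError("A_P must be non-negative")
    cmp = _COMPARATORS[comparator]
    counts = significance_counts(gwas, supportive_traits, p_thresh)
    return set(counts.index[cmp(counts, a_p)])


def map_snps_to_genes(
    snps: set[str] | list[str],
    snp_map: SnpMap,
    genes: GeneAnnotationSet,
    max_dist: int = 2500,
) -> dict[str, str]:
    """Assign each SNP to its nearest gene if within ``max_dist`` bp.

    Distance is 0 inside the gene span, otherwise the distance to the
    nearer span boundary; SNPs farther than ``max_dist`` from every gene
    are dropped (the boundary itself is kept).  Equidistant genes break
    ties by start position then gene id.
    """
    mt = snp_map.table.set_index("snp")
    gt = genes.table
    by_chrom = {c: sub for c, sub in gt.groupby("chrom", sort=False)}
    out: dict[str, str] = {}
    dropped = 0
    for snp in sorted(set(snps)):
        if snp not in mt.index:
            dropped += 1
            continue
        chrom, pos = mt.loc[snp, "chrom"], int(mt.loc[snp, "pos"])
        sub = by_chrom.get(chrom)
        if sub is None:
            dropped += 1
            continue
        start = sub["start"].to_numpy()
        end = sub["end"].to_numpy()
        inside = (pos >= start) & (pos <= end)
        dist = np.where(inside, 0, np.minimum(np.abs(pos - start), np.abs(pos - end)))
        order = np.lexsort((sub["gene"].to_numpy(), start, dist))
        best = order[0]
        if dist[best] <= max_dist:
            out[snp] = sub["gene"].iloc[best]
        else:
            dropped += 1
    if dropped:
        log.info("gene mapping dropped %d SNPs (> %d bp from any gene)", dropped, max_dist)
    return out


def resolve_one_gene_one_snp(
    candidates: dict[str, list[str]],
    gwas: GwasTable,
    snp_map: SnpMap | None = None,
    p_thresh: float = 0.05,
) -> dict[str, str]:
    """Pick one representative SNP per gene.

    Preference: most traits associated at p <= threshold; then lowest
    mean p across all traits; then lowest genomic position; then snp id.
    """
    counts = significance_counts(gwas, gwas.traits, p_thresh)
    mean_p = gwas.pvalues.mean(axis=1)
    pos = (
        snp_map.table.set_index("snp")["pos"]
        if snp_map is not None
        else pd.Series(dtype=float)
    )
    out = {}
    for gene, snps in candidates.items():
        out[gene] = min(
            snps,
            key=lambda s: (
                -int(counts.get(s, 0)),
                float(mean_p.get(s, np.inf)),
                int(pos.get(s, np.iinfo(np.int64).max)),
                s,
            ),
        )
    return out


def inject_custom_snps(gwas: GwasTable, extra: pd.DataFrame) -> tuple[GwasTable, dict[str, str]]:
    """Add externally computed SNP records to the GWAS grid.

    ``extra`` has one row per SNP with columns ``snp``, ``gene``,
    ``effect_<trait>`` and ``p_<trait>`` for every trait in the grid.
    Injected SNPs take part in standardization and every later selection
    step exactly like chip SNPs; the returned mapping pins each injected
    SNP to its stated gene.
    """
    traits = gwas.traits
    eff_cols = {t: f"effect_{t}" for t in traits}
    p_cols = {t: f"p_{t}" for t in traits}
    missing = [c for c in list(eff_cols.values()) + list(p_cols.values()) if c not in extra.columns]
    if missing:
        raise ValueError(f"injected records lack trait columns: {missing}")
    extra = extra.sort_values("snp")  # set semantics: order-independent result
    eff_new = extra.set_index("snp")[[eff_cols[t] for t in traits]]
    eff_new.columns = traits
    p_new = extra.set_index("snp")[[p_cols[t] for t in traits]]
    p_new.columns = traits
    effects = pd.concat([gwas.effects, eff_new.astype(float)])
    pvalues = pd.concat([gwas.pvalues, p_new.astype(float)])
    if effects.index.duplicated().any():
        dup = effects.index[effects.index.duplicated()].tolist()
        raise ValueError(f"injected SNP ids collide with grid SNPs: {dup}")
    gene_map = dict(zip(extra["snp"].astype(str), extra["gene"].astype(str)))
    return GwasTable(effects=effects, pvalues=pvalues), gene_map


def trait_correlation_matrix(traits: TraitTable, method: str = "spearman") -> pd.DataFrame:
    """Pairwise-complete trait correlations (redundancy screen)."""
    vals = traits.values[traits.traits]
    constant = [t for t in vals.columns if vals[t].dropna().nunique() <= 1]
    if constant:
        warnings.warn(f"constant traits yield missing correlations: {constant}", stacklevel=2)
    return vals.corr(method=method, min_periods=3)


def build_awm(
    gwas: GwasTable,
    snp_map: SnpMap,
    genes: GeneAnnotationSet,
    key_traits: list[str],
    supportive_traits: list[str],
    p_thresh: float = 0.05,
    max_dist: int = 2500,
    comparator: str = ">=",
    inject: pd.DataFrame | None = None,
    round_ap: bool = False,
    a_p_override: float | None = None,
) -> AwmMatrix:
    """Run the full selection cascade and assemble the AWM.

    With ``a_p_override`` set (and typically ``key_traits`` empty) the
    key-selection step is skipped and the supplied A_P drives
    supportive-only selection — the construction used for the
    metabolite-only network.
    """
    injected_genes: dict[str, str] = {}
    if inject is not None and len(inject):
        gwas, injected_genes = inject_custom_snps(gwas, inject)
    std = standardize_effects(gwas)

    if a_p_override is None:
        s_key = select_key_snps(gwas, key_traits, p_thresh)
        a_p = compute_ap(gwas, s_key, supportive_traits, p_thresh)
    else:
        s_key = set()
        a_p = float(a_p_override)
    if round_ap:
        a_p = float(np.rint(a_p))
    s_supp = select_supportive_snps(gwas, a_p, supportive_traits, p_thresh, comparator)
    selected = s_key | s_supp
    if not selected:
        raise ValueError("selection cascade admitted no SNPs")

    chip = selected - set(injected_genes)
    snp_to_gene = map_snps_to_genes(chip, snp_map, genes, max_dist)
    for snp, gene in injected_genes.items():
        if snp in selected:
            if gene in set(snp_to_gene.values()):
                log.info("injected SNP %s collides with mapped gene %s", snp, gene)
            snp_to_gene[snp] = gene

    by_gene: dict[str, list[str]] = {}
    for snp, gene in snp_to_gene.items():
        by_gene.setdefault(gene, []).append(snp)
    chosen = resolve_one_gene_one_snp(by_gene, gwas, snp_map, p_thresh)
    if not chosen:
        raise ValueError("no SNP mapped within distance of any gene; AWM is empty")

    pos_lut = snp_map.table.set_index("snp")
    rows = []
    for gene, snp in chosen.items():
        if snp in pos_lut.index:
            chrom, pos = pos_lut.loc[snp, "chrom"], int(pos_lut.loc[snp, "pos"])
        else:  # injected SNP without a map entry: use its gene's span
            grow = genes.table.set_index("gene")
            if gene in grow.index:
                chrom, pos = grow.loc[gene, "chrom"], int(grow.loc[gene, "start"])
            else:
                chrom, pos = "NA", np.iinfo(np.int64).max
        provenance = (
            "injected"
            if snp in injected_genes
            else ("key_selected" if snp in s_key else "supportive_selected")
        )
        rows.append((gene, snp, chrom, pos, provenance))
    info = pd.DataFrame(
        rows, columns=["gene", "snp", "chrom", "pos", "provenance"]
    ).sort_values(["chrom", "pos", "gene"]).set_index("gene")

    values = std.loc[info["snp"].tolist(), list(key_traits) + list(supportive_traits)]
    values.index = info.index
    return AwmMatrix(
        values=values,
        gene_info=info,
        key_traits=list(key_traits),
        supportive_traits=list(supportive_traits),
        a_p=a_p,
    )


def write_awm(awm: AwmMatrix, path) -> None:
    out = pd.concat([awm.gene_info, awm.values], axis=1)
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_awm(path, key_traits: list[str], supportive_traits: list[str], a_p: float = np.nan) -> AwmMatrix:
    tab = pd.read_csv(path, sep="\t", dtype={"gene": str, "snp": str, "chrom": str}).set_index("gene")
    info_cols = ["snp", "chrom", "pos", "provenance"]
    traits = [c for c in tab.columns if c not in info_cols]
    return AwmMatrix(
        values=tab[traits].astype(float),
        gene_info=tab[info_cols],
        key_traits=key_traits,
        supportive_traits=supportive_traits,
        a_p=a_p,
    )
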