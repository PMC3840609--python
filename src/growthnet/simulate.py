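"""Synthetic F2-cross dataset generator with planted pleiotropic modules.

Emulates the study design the pipeline targets: a three-generation cross
between two divergent founder breeds, ~150 male F2 individuals, dense
biallelic SNPs, and 13 phenotypes (2 weight traits + 11 serum
metabolites) falling into four correlation blocks (weights, amino acids,
acylcarnitines, phospho-/sphingolipids).  Ground truth is known: each
planted module is a set of genes whose causal SNPs share an additive
effect vector across traits, so the gene-gene co-association edges the
downstream network should recover are exactly the within-module pairs.

Genotypes descend by Mendelian gene-drop with Haldane (no-interference)
recombination; phenotypes add categorical fixed effects, a pedigree
polygenic term u ~ MVN(0, A*sigma_u2) with block-correlated trait
structure, and iid residuals.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import (
    GeneAnnotationSet,
    GenotypeMatrix,
    Pedigree,
    SnpMap,
    TraitTable,
)
from .gwas import build_a_matrix

TRAIT_BLOCKS: dict[str, tuple[str, ...]] = {
    "weights": ("tw273", "dwg273"),
    "amino_acids": ("arg", "lys"),
    "acylcarnitines": ("C0", "C2", "C5", "C81", "C14", "C18"),
    "lipids": ("PC_aa_C32_0", "PC_ae_C36_1", "SM_C20_2"),
}

TRAITS: tuple[str, ...] = tuple(itertools.chain.from_iterable(TRAIT_BLOCKS.values()))


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedModule:
    """A set of genes whose causal SNPs share a per-trait effect vector."""

    name: str
    genes: tuple[str, ...]
    causal_snps: tuple[str, ...]  # one SNP per gene, same order
    effects: dict[str, float]  # trait -> additive effect (trait SD units)

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.causal_snps):
            raise InvalidConfigError("one causal SNP per gene required")
        if len(set(self.genes)) != len(self.genes):
            raise InvalidConfigError("duplicate genes within a module")


@dataclass(frozen=True)
class SimulationConfig:
    n_founders_per_breed: int = 10
    n_f1: int = 40
    n_f2: int = 150
    n_chromosomes: int = 5
    snps_per_chromosome: int = 200
    chromosome_length_cm: float = 100.0
    snp_spacing_bp: int = 100_000
    founder_allele_freq_range: tuple[float, float] = (0.1, 0.9)
    #: per-breed frequencies of the causal alleles (divergent founders)
    causal_founder_freqs: tuple[float, float] = (0.85, 0.15)
    modules: tuple[PlantedModule, ...] = ()
    polygenic_variance: float = 0.4
    residual_variance: float = 0.6
    #: polygenic correlation between traits of the same block
    within_block_corr: float = 0.6
    #: covariate -> per-level additive shifts (trait SD units)
    fixed_effect_levels: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {"year": (0.0, 0.4, 0.8), "day": (0.0, 0.3)}
    )
    trait_blocks: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(TRAIT_BLOCKS)
    )
    missing_rate: float = 0.0
    gene_halfwidth_bp: int = 1000
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_founders_per_breed < 1:
            raise InvalidConfigError("each founder pool needs at least one animal")
        if not (0 < self.founder_allele_freq_range[0] <= self.founder_allele_freq_range[1] < 1):
            raise InvalidConfigError("founder allele frequencies must lie in (0,1)")
        if self.polygenic_variance < 0 or self.residual_variance <= 0:
            raise InvalidConfigError("variances must be non-negative (residual > 0)")
        traits = list(itertools.chain.from_iterable(self.trait_blocks.values()))
        if len(traits) != len(set(traits)):
            raise InvalidConfigError("trait_blocks must partition traits (duplicates found)")
        all_genes = [g for m in self.modules for g in m.genes]
        if len(all_genes) != len(set(all_genes)):
            raise InvalidConfigError("module gene lists must be disjoint")
        for m in self.modules:
            extra = set(m.effects) - set(traits)
            if extra:
                raise InvalidConfigError(f"module {m.name} effects on unknown traits {extra}")

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(itertools.chain.from_iterable(self.trait_blocks.values()))


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure: within-module gene pairs and causal effects."""

    edges: frozenset  # frozenset({gene_a, gene_b}) pairs sharing a module
    causal_effects: dict[tuple[str, str], float]  # (snp, trait) -> effect
    modules: tuple[PlantedModule, ...]

    def cross_module_pairs(self) -> set[frozenset]:
        out: set[frozenset] = set()
        for ma, mb in itertools.combinations(self.modules, 2):
            for a in ma.genes:
                for b in mb.genes:
                    out.add(frozenset((a, b)))
        return out


# ---------------------------------------------------------------------------
# default desk-scale preset


def _gene_id(chrom: int, idx: int) -> str:
    return f"G{chrom}_{idx:03d}"


def _snp_id(chrom: int, idx: int) -> str:
    return f"snp{chrom}_{idx:03d}"


def default_modules(
    n_modules: int = 3,
    genes_per_module: int = 10,
    key_effect: float = 0.6,
    supportive_effect: float = 0.6,
) -> tuple[PlantedModule, ...]:
    """Three pleiotropic modules with distinct, non-collinear trait patterns.

    Every module loads on both key weight traits (so its genes are
    eligible for key selection) and on a module-specific subset of
    metabolites with mixed signs, keeping cross-module effect profiles
    far from collinear.
    """
    k, s = key_effect, supportive_effect
    patterns = [
        {"tw273": k, "dwg273": k, "arg": s, "lys": s, "C0": s, "C2": s, "C5": s},
        {"tw273": k, "dwg273": k, "arg": -s, "lys": -s, "C81": s, "C14": s, "C18": s},
        {
            "tw273": k,
            "dwg273": k,
            "C0": -s,
            "C2": -s,
            "PC_aa_C32_0": s,
            "PC_ae_C36_1": s,
            "SM_C20_2": s,
        },
    ]
    # Each module owns a disjoint chromosome set, so genotype correlation
    # between modules reflects only the cross design, never physical
    # linkage (an F2 carries founder haplotype blocks tens of cM long).
    # Within a chromosome the module's genes sit in a tight ~1 cM
    # cluster, emulating a major divergent QTL region.
    chrom_sets = [(1, 2), (3, 4), (5,)]
    modules = []
    for m in range(n_modules):
        chroms = chrom_sets[m % len(chrom_sets)]
        per_chrom = -(-genes_per_module // len(chroms))  # ceil
        genes, snps = [], []
        for chrom in chroms:
            for j in range(per_chrom):
                idx = 10 + 2 * j
                genes.append(_gene_id(chrom, idx))
                snps.append(_snp_id(chrom, idx))
        modules.append(
            PlantedModule(
                name=f"module{m + 1}",
                genes=tuple(genes[:genes_per_module]),
                causal_snps=tuple(snps[:genes_per_module]),
                effects=patterns[m % len(patterns)],
            )
        )
    return tuple(modules)


def default_config(seed: int = 42, with_modules: bool = True) -> SimulationConfig:
    """Desk-scale preset: 150 F2, 5 chromosomes x 200 SNPs, 13 traits."""
    return SimulationConfig(
        modules=default_modules() if with_modules else (),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# pedigree


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Three-generation F2 cross: two founder pools -> F1 -> F2."""
    rng = np.random.default_rng(config.seed)
    nb = config.n_founders_per_breed
    breed_a = [f"A{i + 1:03d}" for i in range(nb)]
    breed_b = [f"B{i + 1:03d}" for i in range(nb)]
    rows = [(a, "0", "0", 0, "A") for a in breed_a]
    rows += [(b, "0", "0", 0, "B") for b in breed_b]
    f1 = [f"F1_{i + 1:03d}" for i in range(config.n_f1)]
    for name in f1:
        rows.append((name, rng.choice(breed_a), rng.choice(breed_b), 1, ""))
    if config.n_f2 > 0 and config.n_f1 < 2:
        raise InvalidConfigError("need at least two F1 animals to breed F2")
    for i in range(config.n_f2):
        sire, dam = rng.choice(f1, size=2, replace=False)
        rows.append((f"F2_{i + 1:03d}", sire, dam, 2, ""))
    table = pd.DataFrame(rows, columns=["animal", "sire", "dam", "generation", "breed"])
    return Pedigree(table)


def simulate_snp_map(config: SimulationConfig) -> SnpMap:
    rows = []
    cm_step = config.chromosome_length_cm / max(config.snps_per_chromosome - 1, 1)
    for c in range(1, config.n_chromosomes + 1):
        for i in range(config.snps_per_chromosome):
            rows.append(
                (
                    _snp_id(c, i),
                    str(c),
                    (i + 1) * config.snp_spacing_bp,
                    i * cm_step,
                )
            )
    return SnpMap(pd.DataFrame(rows, columns=["snp", "chrom", "pos", "cm"]))


def generate_annotation(snp_map: SnpMap, halfwidth: int = 1000) -> GeneAnnotationSet:
    """One gene span centred on every SNP (synthetic genome annotation)."""
    tab = snp_map.table
    genes = pd.DataFrame(
        {
            "gene": [s.replace("snp", "G") for s in tab["snp"]],
            "chrom": tab["chrom"],
            "start": np.maximum(tab["pos"] - halfwidth, 1),
            "end": tab["pos"] + halfwidth,
        }
    )
    return GeneAnnotationSet(genes)


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(
    pedigree: Pedigree, snp_map: SnpMap, config: SimulationConfig
) -> GenotypeMatrix:
    """Gene-drop with Haldane recombination; coding minor-count - 1.

    Founders draw haplotypes from Hardy-Weinberg at per-breed, per-SNP
    allele frequencies (causal SNPs use divergent frequencies between
    the breeds).  Descendants inherit one recombinant haplotype from
    each parent; the recombination fraction between adjacent SNPs at map
    distance d cM is (1 - exp(-2d/100))/2.
    """
    if not snp_map.is_sorted_within_chromosome():
        raise ValueError("SNP map must be sorted by position within chromosome")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    tab = snp_map.table
    n_snps = len(tab)
    chrom_slices = [
        (sub.index[0], sub.index[-1] + 1) for _, sub in tab.groupby("chrom", sort=False)
    ]
    cm = tab["cm"].to_numpy(float)
    # per-gap recombination fraction, 0.5 across chromosome boundaries
    rec = np.full(max(n_snps - 1, 0), 0.5)
    for lo, hi in chrom_slices:
        d = np.diff(cm[lo:hi])
        rec[lo : hi - 1] = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))

    # one frequency per SNP, shared by both founder pools; only the
    # planted causal SNPs segregate divergently between the breeds
    lo_f, hi_f = config.founder_allele_freq_range
    base = rng.uniform(lo_f, hi_f, size=n_snps)
    freqs = {"A": base.copy(), "B": base.copy()}
    causal = {s for m in config.modules for s in m.causal_snps}
    snp_index = {s: i for i, s in enumerate(tab["snp"])}
    for s in causal:
        if s not in snp_index:
            raise ValueError(f"causal SNP {s} absent from SNP map")
        freqs["A"][snp_index[s]] = config.causal_founder_freqs[0]
        freqs["B"][snp_index[s]] = config.causal_founder_freqs[1]

    ped = pedigree.table.set_index("animal")
    haplos: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def meiosis(parent: str) -> np.ndarray:
        h1, h2 = haplos[parent]
        start = rng.integers(0, 2)
        cross = rng.random(n_snps - 1) < rec
        which = (start + np.concatenate(([0], np.cumsum(cross)))) % 2
        return np.where(which == 0, h1, h2)

    for animal in pedigree.topological_order():
        if animal not in ped.index:
            raise ValueError(f"unknown animal id {animal}")
        sire, dam = ped.loc[animal, "sire"], ped.loc[animal, "dam"]
        if sire == "0" and dam == "0":
            breed = ped.loc[animal].get("breed", "") or "A"
            p = freqs.get(breed, freqs["A"])
            haplos[animal] = (
                (rng.random(n_snps) < p).astype(np.int8),
                (rng.random(n_snps) < p).astype(np.int8),
            )
        elif sire != "0" and dam != "0":
            haplos[animal] = (meiosis(sire), meiosis(dam))
        else:
            raise ValueError(f"animal {animal} has exactly one known parent")

    animals = pedigree.animals
    counts = np.vstack([haplos[a][0] + haplos[a][1] for a in animals]).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(counts.shape) < config.missing_rate
        counts[mask] = np.nan
    # recode so the counted allele is the dataset minor allele; remember
    # which columns were flipped so planted effects can stay oriented to
    # the breed-A founder allele
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-NaN columns
        freq1 = np.nanmean(counts, axis=0) / 2.0
    flip = freq1 > 0.5
    counts[:, flip] = 2.0 - counts[:, flip]
    values = pd.DataFrame(counts - 1.0, index=animals, columns=tab["snp"].tolist())
    values.attrs["flipped"] = dict(zip(tab["snp"], flip.tolist()))
    return GenotypeMatrix(values)


# ---------------------------------------------------------------------------
# phenotypes


def _block_correlation(config: SimulationConfig) -> np.ndarray:
    traits = list(config.traits)
    t_index = {t: i for i, t in enumerate(traits)}
    corr = np.eye(len(traits))
    for block in config.trait_blocks.values():
        for a, b in itertools.combinations(block, 2):
            corr[t_index[a], t_index[b]] = corr[t_index[b], t_index[a]] = (
                config.within_block_corr
            )
    return corr


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    pedigree: Pedigree,
) -> tuple[TraitTable, GroundTruth]:
    """Phenotypes for the F2 generation plus the planted ground truth.

    y_t = fixed effects + sum_k Z_k * b_(k,t) + u_t + e_t with
    u ~ MVN(0, A * sigma_u2) (block-correlated across traits) and
    iid residuals e ~ N(0, sigma_e2).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    traits = list(config.traits)
    snp_pos = {s: i for i, s in enumerate(genotypes.snps)}
    for m in config.modules:
        for s in m.causal_snps:
            if s not in snp_pos:
                raise ValueError(f"causal SNP {s} absent from genotype matrix")

    ptab = pedigree.table
    if "generation" in ptab.columns:
        target = ptab.loc[ptab["generation"] == ptab["generation"].max(), "animal"]
    else:
        target = ptab["animal"]
    animals = [a for a in target if a in set(genotypes.animals)]
    n = len(animals)
    Z = genotypes.values.loc[animals].to_numpy(float)
    Z = np.nan_to_num(Z, nan=0.0)

    # categorical fixed effects
    cov_cols: dict[str, list[str]] = {}
    fixed_contrib = {}
    for cov, levels in config.fixed_effect_levels.items():
        idx = rng.integers(0, len(levels), size=n)
        cov_cols[cov] = [f"{cov}{i + 1}" for i in idx]
        fixed_contrib[cov] = np.asarray(levels)[idx]
    covariates = pd.DataFrame(cov_cols, index=animals)

    # which covariates act on which trait: weight traits get the first
    # covariate only; metabolite traits get all (year + measurement day)
    cov_names = list(config.fixed_effect_levels)
    weight_traits = set(config.trait_blocks.get("weights", ()))
    fixed_effects = {
        t: (cov_names[0],) if (t in weight_traits and cov_names) else tuple(cov_names)
        for t in traits
    }

    # planted additive effects, oriented to the breed-A founder allele:
    # if the minor-allele recode flipped a causal column, the effect on
    # the *coded* allele changes sign (the ground truth records the
    # coded-allele effect, which is what any downstream estimate sees)
    flipped = genotypes.values.attrs.get("flipped", {})
    B = np.zeros((Z.shape[1], len(traits)))
    causal_effects: dict[tuple[str, str], float] = {}
    for m in config.modules:
        for s in m.causal_snps:
            sign = -1.0 if flipped.get(s, False) else 1.0
            for j, t in enumerate(traits):
                b = sign * float(m.effects.get(t, 0.0))
                if b != 0.0:
                    B[snp_pos[s], j] += b
                causal_effects[(s, t)] = b
    genetic = Z @ B

    # polygenic term with pedigree covariance and block trait correlation
    if config.polygenic_variance > 0 and n > 0:
        A = build_a_matrix(pedigree).loc[animals, animals].to_numpy(float)
        L = np.linalg.cholesky(A + 1e-8 * np.eye(n))
        Lb = np.linalg.cholesky(_block_correlation(config) + 1e-10 * np.eye(len(traits)))
        U = np.sqrt(config.polygenic_variance) * (L @ rng.standard_normal((n, len(traits))) @ Lb.T)
    else:
        U = np.zeros((n, len(traits)))
    E = np.sqrt(config.residual_variance) * rng.standard_normal((n, len(traits)))

    Y = genetic + U + E
    for j, t in enumerate(traits):
        for cov in fixed_effects[t]:
            Y[:, j] += fixed_contrib[cov]

    values = pd.DataFrame(Y, index=animals, columns=traits)
    roles = {t: ("key" if t in weight_traits else "supportive") for t in traits}
    table = TraitTable(values, covariates, roles, fixed_effects)

    edges = frozenset(
        frozenset(pair)
        for m in config.modules
        for pair in itertools.combinations(m.genes, 2)
    )
    truth = GroundTruth(edges=edges, causal_effects=causal_effects, modules=config.modules)
    return table, truth


def simulate_dataset(config: SimulationConfig):
    """Convenience: pedigree, map, annotation, genotypes, phenotypes, truth."""
    ped = simulate_pedigree(config)
    snp_map = simulate_snp_map(config)
    genes = generate_annotation(snp_map, config.gene_halfwidth_bp)
    geno = simulate_genotypes(ped, snp_map, config)
    traits, truth = simulate_phenotypes(geno, config, ped)
    return ped, snp_map, genes, geno, traits, truth


def null_config(seed: int, **overrides) -> SimulationConfig:
    """A no-module configuration (pure polygenic + noise) for calibration."""
    cfg = default_config(seed=seed, with_modules=False)
    return replace(cfg, **overrides) if overrides else cfg
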