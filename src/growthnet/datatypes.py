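"""Core in-memory containers shared across the pipeline.

All tables are thin wrappers around :class:`pandas.DataFrame` with the
validation the pipeline relies on: unique identifiers, consistent
dimensions, and (for pedigrees) an acyclic ancestry graph.  Coordinates
are 1-based inclusive throughout.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

UNKNOWN_PARENT = "0"

#: allowed genotype codes: minor-allele count minus one, NaN = missing
GENOTYPE_CODES = (-1.0, 0.0, 1.0)


class CyclicPedigreeError(ValueError):
    """Raised when an animal appears among its own ancestors."""


@dataclass
class Pedigree:
    """Pedigree records (animal, sire, dam), ``"0"`` meaning unknown.

    ``table`` may carry extra columns (e.g. ``generation``, ``breed``
    from the simulator); only the first three are contractual.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["animal", "sire", "dam"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"pedigree table lacks columns {missing}")
        tab = self.table.copy()
        for c in required:
            tab[c] = tab[c].astype(str)
        if tab["animal"].duplicated().any():
            dups = tab.loc[tab["animal"].duplicated(), "animal"].tolist()
            raise ValueError(f"duplicate animal ids in pedigree: {dups}")
        known = set(tab["animal"])
        for c in ("sire", "dam"):
            bad = sorted(set(tab[c]) - known - {UNKNOWN_PARENT})
            if bad:
                raise ValueError(f"{c} ids not in pedigree: {bad}")
        self.table = tab.reset_index(drop=True)
        self.topological_order()  # raises CyclicPedigreeError on cycles

    @property
    def animals(self) -> list[str]:
        return self.table["animal"].tolist()

    def parents(self, animal: str) -> tuple[str | None, str | None]:
        row = self.table.set_index("animal").loc[animal]
        sire = None if row["sire"] == UNKNOWN_PARENT else row["sire"]
        dam = None if row["dam"] == UNKNOWN_PARENT else row["dam"]
        return sire, dam

    def topological_order(self) -> list[str]:
        """Animals sorted so every parent precedes its offspring."""
        g = nx.DiGraph()
        g.add_nodes_from(self.table["animal"])
        for _, row in self.table.iterrows():
            for p in (row["sire"], row["dam"]):
                if p != UNKNOWN_PARENT:
                    g.add_edge(p, row["animal"])
        try:
            order = list(nx.topological_sort(g))
        except nx.NetworkXUnfeasible as exc:
            cycle = nx.find_cycle(g)
            raise CyclicPedigreeError(
                f"pedigree contains an ancestry cycle: {cycle}"
            ) from exc
        # sort by generation depth, stable within a generation
        depth: dict[str, int] = {}
        parents = dict(
            zip(self.table["animal"], zip(self.table["sire"], self.table["dam"]))
        )
        for a in order:
            ds = [depth[p] for p in parents[a] if p != UNKNOWN_PARENT]
            depth[a] = 1 + max(ds) if ds else 0
        rank = {a: i for i, a in enumerate(self.table["animal"])}
        return sorted(order, key=lambda a: (depth[a], rank[a]))

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SnpMap:
    """Marker map: snp id, chromosome, bp position (1-based), optional cM."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["snp", "chrom", "pos"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"SNP map lacks columns {missing}")
        tab = self.table.copy()
        tab["snp"] = tab["snp"].astype(str)
        tab["chrom"] = tab["chrom"].astype(str)
        tab["pos"] = tab["pos"].astype(np.int64)
        if "cm" not in tab.columns:
            tab["cm"] = np.nan
        if tab["snp"].duplicated().any():
            raise ValueError("duplicate snp ids in map")
        if (tab["pos"] < 1).any():
            raise ValueError("bp positions must be >= 1")
        self.table = tab.reset_index(drop=True)

    @property
    def snps(self) -> list[str]:
        return self.table["snp"].tolist()

    def is_sorted_within_chromosome(self) -> bool:
        for _, sub in self.table.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                return False
        return True

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs, values in {-1, 0, +1}, NaN = missing."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.values.astype(float)
        arr = vals.to_numpy()
        ok = np.isnan(arr) | np.isin(arr, GENOTYPE_CODES)
        if not ok.all():
            bad = np.unique(arr[~ok])
            raise ValueError(f"genotype codes outside {{-1,0,1,NaN}}: {bad}")
        if vals.index.duplicated().any() or vals.columns.duplicated().any():
            raise ValueError("duplicate animal or snp ids in genotype matrix")
        self.values = vals

    @property
    def animals(self) -> list[str]:
        return list(self.values.index)

    @property
    def snps(self) -> list[str]:
        return list(self.values.columns)

    def call_rate_per_snp(self) -> pd.Series:
        return self.values.notna().mean(axis=0)

    def call_rate_per_sample(self) -> pd.Series:
        return self.values.notna().mean(axis=1)

    def maf(self) -> pd.Series:
        """Minor allele frequency per SNP (codes are minor-allele count - 1)."""
        freq = (self.values + 1).mean(axis=0, skipna=True) / 2.0
        return np.minimum(freq, 1.0 - freq)


@dataclass
class GeneAnnotationSet:
    """Gene spans: gene id, chromosome, start, end (1-based inclusive)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene", "chrom", "start", "end"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation lacks columns {missing}")
        tab = self.table.copy()
        tab["gene"] = tab["gene"].astype(str)
        tab["chrom"] = tab["chrom"].astype(str)
        tab["start"] = tab["start"].astype(np.int64)
        tab["end"] = tab["end"].astype(np.int64)
        if tab["gene"].duplicated().any():
            raise ValueError("duplicate gene ids in annotation")
        if (tab["start"] > tab["end"]).any():
            bad = tab.loc[tab["start"] > tab["end"], "gene"].tolist()
            raise ValueError(f"start > end for genes: {bad}")
        self.table = tab.reset_index(drop=True)

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class TraitTable:
    """Phenotypes (numeric traits) + categorical covariates + trait roles.

    ``roles`` maps each analyzed trait to ``"key"`` or ``"supportive"``.
    ``fixed_effects`` optionally maps a trait to the covariate columns
    fitted for it (default: all covariate columns) — the study design
    fits different fixed effects for weight and metabolite traits.
    """

    values: pd.DataFrame
    covariates: pd.DataFrame
    roles: dict[str, str]
    fixed_effects: dict[str, tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        absent = [t for t in self.roles if t not in self.values.columns]
        if absent:
            raise ValueError(f"roles reference absent traits: {absent}")
        bad = {t: r for t, r in self.roles.items() if r not in ("key", "supportive")}
        if bad:
            raise ValueError(f"invalid trait roles: {bad}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate animal ids in phenotype table")
        if not self.values.index.equals(self.covariates.index):
            self.covariates = self.covariates.reindex(self.values.index)
        if self.fixed_effects is not None:
            for t, cols in self.fixed_effects.items():
                miss = [c for c in cols if c not in self.covariates.columns]
                if miss:
                    raise ValueError(f"fixed-effect columns absent for {t}: {miss}")

    @property
    def traits(self) -> list[str]:
        return [t for t in self.values.columns if t in self.roles]

    @property
    def key_traits(self) -> list[str]:
        return [t for t in self.traits if self.roles[t] == "key"]

    @property
    def supportive_traits(self) -> list[str]:
        return [t for t in self.traits if self.roles[t] == "supportive"]

    def covariate_columns_for(self, trait: str) -> list[str]:
        if self.fixed_effects and trait in self.fixed_effects:
            return list(self.fixed_effects[trait])
        return list(self.covariates.columns)


@dataclass
class GwasTable:
    """SNP x trait grid of additive effects, LRT statistics and p-values."""

    effects: pd.DataFrame
    pvalues: pd.DataFrame
    lrt: pd.DataFrame | None = None
    n_used: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.effects.index.equals(self.pvalues.index) or not self.effects.columns.equals(
            self.pvalues.columns
        ):
            raise ValueError("effects and pvalues grids are not aligned")
        p = self.pvalues.to_numpy(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # NaN comparisons
            if np.nanmin(p) <= 0 or np.nanmax(p) > 1:
                raise ValueError("p-values must lie in (0, 1]")

    @property
    def snps(self) -> list[str]:
        return list(self.effects.index)

    @property
    def traits(self) -> list[str]:
        return list(self.effects.columns)


@dataclass
class AwmMatrix:
    """Association weight matrix: genes x traits of standardized effects.

    ``gene_info`` (indexed by gene) records the representative SNP, its
    chromosome/position and selection provenance
    (key_selected / supportive_selected / injected).
    """

    values: pd.DataFrame
    gene_info: pd.DataFrame
    key_traits: list[str]
    supportive_traits: list[str]
    a_p: float

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate genes in AWM")
        if not self.values.index.equals(self.gene_info.index):
            raise ValueError("AWM values and gene_info indices differ")
        if not np.isfinite(self.values.to_numpy(float)).all():
            raise ValueError("AWM cells must be finite")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CoassociationNetwork:
    """Genes as nodes, undirected PCIT-significant edges with signed r.

    Isolated genes may be present as nodes; ``n_genes`` follows the
    counting rule of the analysis (nodes with at least one edge).
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("self-loops are not allowed")

    @property
    def n_genes(self) -> int:
        return sum(1 for _, d in self.graph.degree if d > 0)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def max_degree(self) -> int:
        degs = [d for _, d in self.graph.degree]
        return max(degs) if degs else 0

    def edge_set(self) -> set[frozenset]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    def correlation(self, u: str, v: str) -> float:
        return float(self.graph.edges[u, v]["r"])
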