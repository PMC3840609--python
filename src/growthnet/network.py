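"""Downstream network analysis: hubs, permutation nulls, subnetworks, MCODE.

Mirrors the analysis a co-association study performs once the PCIT
network exists: degree/hub tables, validation against column-permuted
random AWMs (the permutation destroys SNP-trait association structure
while preserving every column's marginal distribution), a
metabolite-only network and its overlap with the full network,
gene-centric ego subnetworks, and MCODE dense-cluster extraction.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .awm import build_awm
from .datatypes import (
    AwmMatrix,
    CoassociationNetwork,
    GeneAnnotationSet,
    GwasTable,
    SnpMap,
)
from .pcit import network_from_awm

log = logging.getLogger(__name__)


def degree_table(network: CoassociationNetwork) -> pd.DataFrame:
    """Per-gene connectivity, sorted by degree (desc) then gene id."""
    rows = sorted(network.graph.degree, key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["gene", "degree"])


# ---------------------------------------------------------------------------
# permutation null


def randomize_awm(awm: AwmMatrix, seed: int) -> AwmMatrix:
    """Independently permute every trait column across genes."""
    if not len(awm):
        raise ValueError("cannot randomize an empty AWM")
    rng = np.random.default_rng(seed)
    vals = awm.values.to_numpy(float).copy()
    for j in range(vals.shape[1]):
        vals[:, j] = vals[rng.permutation(vals.shape[0]), j]
    values = pd.DataFrame(vals, index=awm.values.index, columns=awm.values.columns)
    return AwmMatrix(
        values=values,
        gene_info=awm.gene_info,
        key_traits=awm.key_traits,
        supportive_traits=awm.supportive_traits,
        a_p=awm.a_p,
    )


@dataclass
class RandomizationSummary:
    """Node/edge/degree statistics across column-permuted replicates."""

    replicates: pd.DataFrame  # columns: nodes, edges, max_degree
    mean_nodes: float
    mean_edges: float
    mean_max_degree: float
    per_gene_mean_degree: pd.Series
    seed: int


def random_validation(
    awm: AwmMatrix,
    n_replicates: int = 10,
    pc_threshold: float = 0.80,
    seed: int = 0,
    method: str = "fast",
) -> RandomizationSummary:
    """Build ``n_replicates`` permuted-AWM networks and summarize them.

    Replicate seeds are derived deterministically as seed + index.
    """
    rows = []
    deg_sum = pd.Series(0.0, index=awm.genes)
    for i in range(n_replicates):
        rnd = randomize_awm(awm, seed=(seed + i) % 2**31)
        net, _, _ = network_from_awm(rnd, pc_threshold, method=method)
        rows.append((net.n_genes, net.n_edges, net.max_degree))
        deg = pd.Series(dict(net.graph.degree), dtype=float)
        deg_sum = deg_sum.add(deg, fill_value=0.0)
    reps = pd.DataFrame(rows, columns=["nodes", "edges", "max_degree"])
    return RandomizationSummary(
        replicates=reps,
        mean_nodes=float(reps["nodes"].mean()),
        mean_edges=float(reps["edges"].mean()),
        mean_max_degree=float(reps["max_degree"].mean()),
        per_gene_mean_degree=deg_sum / n_replicates,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# metabolite-only network and overlap


def metabolite_only_network(
    gwas: GwasTable,
    snp_map: SnpMap,
    genes: GeneAnnotationSet,
    supportive_traits: list[str],
    a_p_from_full: float,
    p_thresh: float = 0.05,
    max_dist: int = 2500,
    comparator: str = ">=",
    pc_threshold: float = 0.80,
    inject: pd.DataFrame | None = None,
    method: str = "fast",
) -> tuple[CoassociationNetwork, AwmMatrix | None]:
    """Network built from the supportive (metabolite) traits alone.

    Key-trait columns are removed from the grids; SNPs are selected by
    their supportive hit count against the A_P of the *full* analysis;
    the usual AWM -> PCIT -> |r| threshold cascade follows.
    """
    keep = [t for t in gwas.traits if t in supportive_traits]
    reduced = GwasTable(
        effects=gwas.effects[keep],
        pvalues=gwas.pvalues[keep],
        lrt=gwas.lrt[keep] if gwas.lrt is not None else None,
    )
    if inject is not None and len(inject):
        cols = ["snp", "gene"] + [f"effect_{t}" for t in keep] + [f"p_{t}" for t in keep]
        inject = inject[[c for c in cols if c in inject.columns]]
    try:
        awm = build_awm(
            reduced,
            snp_map,
            genes,
            key_traits=[],
            supportive_traits=keep,
            p_thresh=p_thresh,
            max_dist=max_dist,
            comparator=comparator,
            inject=inject,
            a_p_override=a_p_from_full,
        )
    except ValueError as exc:
        warnings.warn(f"metabolite-only selection admitted nothing: {exc}", stacklevel=2)
        return CoassociationNetwork(nx.Graph()), None
    if len(awm) < 3:
        warnings.warn("metabolite-only AWM too small for PCIT; empty network", stacklevel=2)
        return CoassociationNetwork(nx.Graph()), awm
    net, _, _ = network_from_awm(awm, pc_threshold, method=method)
    return net, awm


def overlap(
    net_a: CoassociationNetwork, net_b: CoassociationNetwork
) -> tuple[set[str], set[frozenset]]:
    """Shared nodes and shared undirected edges of two networks."""
    nodes = set(net_a.graph.nodes) & set(net_b.graph.nodes)
    edges = net_a.edge_set() & net_b.edge_set()
    return nodes, edges


# ---------------------------------------------------------------------------
# gene-centric subnetworks


def gene_subnetwork(network: CoassociationNetwork, gene: str) -> CoassociationNetwork:
    """The gene, its direct partners, and ALL edges among those nodes."""
    if gene not in network.graph:
        raise KeyError(f"gene {gene} not in network")
    nodes = {gene} | set(network.graph[gene])
    return CoassociationNetwork(network.graph.subgraph(nodes).copy())


# ---------------------------------------------------------------------------
# MCODE


@dataclass
class NetworkCluster:
    """A dense region found by MCODE."""

    members: tuple[str, ...]
    seed_gene: str
    score: float
    within_degree: dict[str, int]

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


def _vertex_weights(g: nx.Graph, degree_cutoff: int) -> dict[str, float]:
    """Core-clustering-coefficient weights.

    weight(v) = k * density of the highest k-core of v's closed
    neighborhood; vertices below the degree cutoff weigh 0 and cannot
    seed clusters.
    """
    weights: dict[str, float] = {}
    for v in g:
        if g.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = set(g[v]) | {v}
        sub = g.subgraph(nbhd)
        core = nx.core_number(sub)
        k = max(core.values())
        if k == 0:
            weights[v] = 0.0
            continue
        kcore = sub.subgraph([u for u, c in core.items() if c >= k])
        weights[v] = k * nx.density(kcore)
    return weights


def mcode_clusters(
    network: CoassociationNetwork,
    degree_cutoff: int = 2,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
    haircut: bool = True,
    fluff: bool = False,
    max_depth: int = 100,
) -> list[NetworkCluster]:
    """MCODE dense-cluster detection at its published default settings.

    Stage 1 weights every vertex by its core-clustering coefficient;
    stage 2 grows a complex from each highest-weight unvisited seed,
    admitting neighbors whose weight is within ``node_score_cutoff`` of
    the seed's; stage 3 discards complexes lacking a ``k_core`` and
    optionally shaves singly-connected members (haircut).  ``fluff`` is
    accepted for interface completeness and not applied when False.
    """
    g = network.graph
    if fluff:
        raise NotImplementedError("fluff post-processing is not supported")
    w = _vertex_weights(g, degree_cutoff)
    order = sorted(g.nodes, key=lambda v: (-w[v], v))
    seen: set[str] = set()
    clusters: list[NetworkCluster] = []
    for seedv in order:
        if seedv in seen or w[seedv] <= 0.0:
            continue
        threshold = w[seedv] * (1.0 - node_score_cutoff)
        members = {seedv}
        frontier = [seedv]
        depth = 0
        while frontier and depth < max_depth:
            nxt = []
            for u in frontier:
                for nb in g[u]:
                    if nb in members or nb in seen:
                        continue
                    if w[nb] >= threshold:
                        members.add(nb)
                        nxt.append(nb)
            frontier = nxt
            depth += 1
        seen |= members
        sub = g.subgraph(members).copy()
        core = nx.k_core(sub, k_core)
        if core.number_of_nodes() == 0:
            continue
        if haircut:
            shave = [v for v in sub if sub.degree(v) < 2]
            sub.remove_nodes_from(shave)
        if sub.number_of_nodes() < 2:
            continue
        score = nx.density(sub) * sub.number_of_nodes()
        clusters.append(
            NetworkCluster(
                members=tuple(sorted(sub.nodes)),
                seed_gene=seedv,
                score=float(score),
                within_degree={v: int(d) for v, d in sub.degree},
            )
        )
    clusters.sort(key=lambda c: (-c.score, -len(c.members), c.members))
    return clusters


def dense_subnetwork(network: CoassociationNetwork, gene: str, **mcode_kwargs) -> NetworkCluster:
    """MCODE cluster of the query gene within its ego subnetwork."""
    ego = gene_subnetwork(network, gene)
    clusters = mcode_clusters(ego, **mcode_kwargs)
    for c in clusters:
        if gene in c:
            return c
    warnings.warn(f"{gene} not in any dense cluster of its ego network", stacklevel=2)
    if clusters:
        return clusters[0]
    deg = dict(ego.graph.degree)
    return NetworkCluster(
        members=tuple(sorted(ego.graph.nodes)),
        seed_gene=gene,
        score=0.0,
        within_degree={v: int(d) for v, d in deg.items()},
    )
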