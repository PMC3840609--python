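"""One-command driver: data -> GWAS -> AWM -> PCIT -> network analyses.

``run_all`` executes the full study flow on either a simulated dataset
(the default desk-scale preset) or user-supplied files, writing every
intermediate table, a machine-readable ``summary.json`` and a config
snapshot sufficient to reproduce the run bit-identically.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import awm as awm_mod
from . import enrich as enrich_mod
from . import gwas as gwas_mod
from . import io as io_mod
from . import network as net_mod
from . import simulate as sim_mod
from .pcit import network_from_awm

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage '{stage}' failed: {exc}")
        self.stage = stage
        self.cause = exc


@dataclass
class RunConfig:
    out_dir: str = "growthnet_run"
    seed: int = 42
    # data source: simulate (default) or explicit file paths
    simulate: bool = True
    #: scalar overrides applied to the default SimulationConfig preset
    sim_overrides: dict | None = None
    geno_ped: str | None = None
    geno_map: str | None = None
    pedigree: str | None = None
    phenotypes: str | None = None
    genes: str | None = None
    roles: dict[str, str] | None = None
    fixed_effects: dict[str, tuple[str, ...]] | None = None
    # thresholds
    p_thresh: float = 0.05
    max_dist: int = 2500
    pc_threshold: float = 0.80
    n_random: int = 10
    comparator: str = ">="
    metabolite_comparator: str = ">="
    round_ap: bool = False
    hub_count: int = 10
    # optional enrichment inputs
    enrichment_annotation: str | None = None
    enrichment_reference: str | None = None

    def validate(self) -> None:
        if not (0 <= self.p_thresh <= 1):
            raise ValueError("p_thresh must lie in [0, 1]")
        if not (0 <= self.pc_threshold <= 1):
            raise ValueError("pc_threshold must lie in [0, 1]")
        if self.max_dist < 0 or self.n_random < 0:
            raise ValueError("max_dist and n_random must be non-negative")
        if self.comparator not in (">=", ">") or self.metabolite_comparator not in (">=", ">"):
            raise ValueError("comparators must be '>=' or '>'")
        if not self.simulate:
            needed = ["geno_ped", "geno_map", "pedigree", "phenotypes", "genes"]
            missing = [k for k in needed if getattr(self, k) is None]
            if missing:
                raise ValueError(f"file mode requires paths: {missing}")
            if not self.roles:
                raise ValueError("file mode requires a trait-role mapping")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc

        return wrapped

    return deco


def run_all(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- data ------------------------------------------------------------
    try:
        if config.simulate:
            sim_cfg = sim_mod.default_config(seed=config.seed)
            if config.sim_overrides:
                sim_cfg = dataclasses.replace(sim_cfg, **config.sim_overrides)
            ped, snp_map, genes, geno, traits, truth = sim_mod.simulate_dataset(sim_cfg)
            data_dir = out / "data"
            data_dir.mkdir(exist_ok=True)
            io_mod.write_genotypes(geno, data_dir / "genotypes.ped", data_dir / "genotypes.map", snp_map, ped)
            io_mod.write_pedigree(ped, data_dir / "pedigree.tsv")
            io_mod.write_phenotypes(traits, data_dir / "phenotypes.tsv")
            io_mod.write_annotation(genes, data_dir / "genes.tsv")
            pd.DataFrame(
                sorted(tuple(sorted(e)) for e in truth.edges),
                columns=["gene_a", "gene_b"],
            ).to_csv(data_dir / "ground_truth_edges.tsv", sep="\t", index=False)
        else:
            geno, snp_map = io_mod.read_genotypes(config.geno_ped, config.geno_map)
            ped = io_mod.read_pedigree(config.pedigree)
            traits = io_mod.read_phenotypes(config.phenotypes, config.roles, config.fixed_effects)
            genes = io_mod.read_annotation(config.genes)
    except Exception as exc:
        raise StageError("data", exc) from exc

    summary: dict = {
        "seed": config.seed,
        "thresholds": {
            "p_thresh": config.p_thresh,
            "max_dist": config.max_dist,
            "pc_threshold": config.pc_threshold,
            "n_random": config.n_random,
            "comparator": config.comparator,
            "metabolite_comparator": config.metabolite_comparator,
        },
    }

    # ---- qc + gwas -------------------------------------------------------
    try:
        geno_qc = gwas_mod.qc_filter(geno)
        summary["qc"] = {"n_samples": len(geno_qc.animals), "n_snps": len(geno_qc.snps)}
        gwas = gwas_mod.run_gwas(geno_qc, traits, ped)
        io_mod.write_gwas(gwas, out / "gwas.tsv")
    except Exception as exc:
        raise StageError("gwas", exc) from exc

    # ---- awm -------------------------------------------------------------
    try:
        awm = awm_mod.build_awm(
            gwas,
            snp_map,
            genes,
            key_traits=traits.key_traits,
            supportive_traits=traits.supportive_traits,
            p_thresh=config.p_thresh,
            max_dist=config.max_dist,
            comparator=config.comparator,
            round_ap=config.round_ap,
        )
        awm_mod.write_awm(awm, out / "awm.tsv")
        summary["awm"] = {"n_genes": len(awm), "a_p": awm.a_p}
    except Exception as exc:
        raise StageError("awm", exc) from exc

    # ---- pcit network ----------------------------------------------------
    try:
        net, r, sig = network_from_awm(awm, config.pc_threshold)
        io_mod.write_network(net, out / "network")
        hubs = net_mod.degree_table(net)
        hubs.head(config.hub_count).to_csv(out / "hubs.tsv", sep="\t", index=False)
        summary["network"] = {
            "n_genes": net.n_genes,
            "n_edges": net.n_edges,
            "max_degree": net.max_degree,
        }
    except Exception as exc:
        raise StageError("pcit", exc) from exc

    # ---- random validation ----------------------------------------------
    try:
        rand = net_mod.random_validation(
            awm, config.n_random, config.pc_threshold, seed=config.seed
        )
        rand.replicates.to_csv(out / "random_replicates.tsv", sep="\t", index=False)
        summary["random_networks"] = {
            "mean_nodes": rand.mean_nodes,
            "mean_edges": rand.mean_edges,
            "mean_max_degree": rand.mean_max_degree,
            "max_degree_overall": int(rand.replicates["max_degree"].max()),
        }
    except Exception as exc:
        raise StageError("random_validation", exc) from exc

    # ---- metabolite-only network + overlap -------------------------------
    try:
        met_net, met_awm = net_mod.metabolite_only_network(
            gwas,
            snp_map,
            genes,
            supportive_traits=traits.supportive_traits,
            a_p_from_full=awm.a_p,
            p_thresh=config.p_thresh,
            max_dist=config.max_dist,
            comparator=config.metabolite_comparator,
            pc_threshold=config.pc_threshold,
        )
        io_mod.write_network(met_net, out / "metabolite_network")
        shared_nodes, shared_edges = net_mod.overlap(net, met_net)
        summary["metabolite_network"] = {
            "n_genes": met_net.n_genes,
            "n_edges": met_net.n_edges,
            "overlap_nodes": len(shared_nodes),
            "overlap_edges": len(shared_edges),
        }
    except Exception as exc:
        raise StageError("metabolite_network", exc) from exc

    # ---- dense clusters and hub subnetwork -------------------------------
    try:
        clusters = net_mod.mcode_clusters(net)
        pd.DataFrame(
            [
                (i + 1, c.score, len(c.members), c.seed_gene, ";".join(c.members))
                for i, c in enumerate(clusters)
            ],
            columns=["rank", "score", "n_members", "seed_gene", "members"],
        ).to_csv(out / "mcode_clusters.tsv", sep="\t", index=False)
        summary["mcode"] = {
            "n_clusters": len(clusters),
            "top_score": clusters[0].score if clusters else 0.0,
        }
        if net.n_edges > 0:
            top_hub = hubs.iloc[0]["gene"]
            sub = net_mod.gene_subnetwork(net, top_hub)
            io_mod.write_network(sub, out / f"subnetwork_{top_hub}")
            summary["top_hub"] = {
                "gene": str(top_hub),
                "degree": int(hubs.iloc[0]["degree"]),
            }
    except Exception as exc:
        raise StageError("clusters", exc) from exc

    # ---- optional enrichment ---------------------------------------------
    if config.enrichment_annotation and config.enrichment_reference:
        try:
            ann = pd.read_csv(config.enrichment_annotation, sep="\t")
            ref = set(
                Path(config.enrichment_reference).read_text().split()
            )
            netg = {g for g, d in net.graph.degree if d > 0}
            table = enrich_mod.binomial_enrichment(netg, ref, ann)
            table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            summary["enrichment"] = {"n_terms": int(len(table))}
        except Exception as exc:
            raise StageError("enrichment", exc) from exc

    # ---- snapshot --------------------------------------------------------
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    snapshot = dataclasses.asdict(config)
    with open(out / "config_snapshot.yaml", "w") as fh:
        yaml.safe_dump(snapshot, fh, sort_keys=True)
    log.info("run complete: %s", out)
    return out
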