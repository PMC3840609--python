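"""AWM assembly: standardization, selection cascade, gene mapping, injection."""
import itertools

import numpy as np
import pandas as pd
import pytest

from growthnet.awm import (
    build_awm,
    compute_ap,
    inject_custom_snps,
    map_snps_to_genes,
    resolve_one_gene_one_snp,
    select_key_snps,
    select_supportive_snps,
    standardize_effects,
    trait_correlation_matrix,
)
from growthnet.datatypes import GeneAnnotationSet, GwasTable, SnpMap, TraitTable


def _grid(pvals: dict, effects: dict | None = None, traits=("K", "S1", "S2", "S3")):
    snps = list(pvals)
    p = pd.DataFrame([pvals[s] for s in snps], index=snps, columns=list(traits))
    if effects is None:
        rng = np.random.default_rng(0)
        e = pd.DataFrame(rng.standard_normal((len(snps), len(traits))),
                         index=snps, columns=list(traits))
    else:
        e = pd.DataFrame([effects[s] for s in snps], index=snps, columns=list(traits))
    return GwasTable(effects=e, pvalues=p)


@pytest.fixture()
def cascade_fixture():
    """Hand-designed 8-SNP grid whose selection cascade was walked on paper.

    S_key = {s1,s2,s5,s7}; supportive counts (2,1,1,0) give A_P = 1.0;
    s5/s8 map to no gene within 2500 bp; s1 beats s2 for gene gA.
    """
    pvals = {
        "s1": [0.01, 0.01, 0.04, 0.50],
        "s2": [0.04, 0.03, 0.50, 0.60],
        "s3": [0.20, 0.04, 0.03, 0.90],
        "s4": [0.50, 0.01, 0.90, 0.90],
        "s5": [0.01, 0.02, 0.90, 0.90],
        "s6": [0.90, 0.90, 0.90, 0.90],
        "s7": [0.05, 0.90, 0.90, 0.90],
        "s8": [0.90, 0.01, 0.90, 0.90],
    }
    gwas = _grid(pvals)
    snp_map = SnpMap(pd.DataFrame({
        "snp": list(pvals),
        "chrom": "1",
        "pos": [1000, 2000, 10000, 20000, 50000, 60000, 70000, 90000],
    }))
    genes = GeneAnnotationSet(pd.DataFrame({
        "gene": ["gA", "gB", "gC", "gD"],
        "chrom": "1",
        "start": [500, 9000, 19000, 69000],
        "end": [2500, 11000, 21000, 71000],
    }))
    return gwas, snp_map, genes


class TestStandardize:
    def test_already_standard_unchanged(self, rng):
        vals = rng.standard_normal((50, 3))
        vals = (vals - vals.mean(0)) / vals.std(0, ddof=1)
        gwas = GwasTable(
            effects=pd.DataFrame(vals, columns=list("abc")),
            pvalues=pd.DataFrame(np.full((50, 3), 0.5), columns=list("abc")),
        )
        out = standardize_effects(gwas)
        np.testing.assert_allclose(out.to_numpy(), vals, atol=1e-12)

    def test_one_two_three_becomes_z_scores(self):
        gwas = GwasTable(
            effects=pd.DataFrame({"t": [1.0, 2.0, 3.0]}),
            pvalues=pd.DataFrame({"t": [0.5, 0.5, 0.5]}),
        )
        out = standardize_effects(gwas)
        np.testing.assert_allclose(out["t"].to_numpy(), [-1.0, 0.0, 1.0], atol=1e-12)

    def test_columns_have_zero_mean_unit_sd(self, rng):
        gwas = GwasTable(
            effects=pd.DataFrame(rng.standard_normal((30, 4)) * 5 + 2),
            pvalues=pd.DataFrame(np.full((30, 4), 0.5)),
        )
        out = standardize_effects(gwas)
        assert (out.mean().abs() < 1e-10).all()
        assert (out.std(ddof=1) - 1).abs().max() < 1e-10

    def test_zero_variance_column_names_trait(self):
        gwas = GwasTable(
            effects=pd.DataFrame({"flat": [1.0, 1.0], "ok": [0.0, 1.0]}),
            pvalues=pd.DataFrame({"flat": [0.5, 0.5], "ok": [0.5, 0.5]}),
        )
        with pytest.raises(ValueError, match="flat"):
            standardize_effects(gwas)


class TestSelection:
    def test_boundary_p_is_inclusive(self, cascade_fixture):
        gwas, _, _ = cascade_fixture
        assert "s7" in select_key_snps(gwas, ["K"])  # p = 0.05 exactly

    def test_supportive_only_snp_excluded_from_key(self, cascade_fixture):
        gwas, _, _ = cascade_fixture
        assert "s3" not in select_key_snps(gwas, ["K"])

    def test_key_selection_matches_brute_force(self, rng):
        p = pd.DataFrame(rng.uniform(0, 1, (20, 4)), columns=list("KABC"),
                         index=[f"s{i}" for i in range(20)])
        gwas = GwasTable(effects=p * 0 + 1.0 * rng.standard_normal((20, 4)), pvalues=p)
        got = select_key_snps(gwas, ["K", "A"], 0.3)
        expected = {s for s in p.index if p.loc[s, "K"] <= 0.3 or p.loc[s, "A"] <= 0.3}
        assert got == expected

    def test_key_selection_monotone_in_threshold(self, rng):
        p = pd.DataFrame(rng.uniform(0, 1, (30, 3)), columns=list("KAB"))
        gwas = GwasTable(effects=p * 0.0, pvalues=p)
        prev = set()
        for t in (0.01, 0.05, 0.2, 0.9):
            cur = select_key_snps(gwas, ["K"], t)
            assert prev <= cur
            prev = cur

    def test_ap_arithmetic_mean(self, cascade_fixture):
        gwas, _, _ = cascade_fixture
        s_key = select_key_snps(gwas, ["K"])
        assert compute_ap(gwas, s_key, ["S1", "S2", "S3"]) == pytest.approx(1.0)

    def test_ap_zero_warns(self):
        gwas = _grid({"s1": [0.01, 0.9, 0.9, 0.9], "s2": [0.9, 0.9, 0.9, 0.9]})
        with pytest.warns(UserWarning, match="A_P is 0"):
            ap = compute_ap(gwas, {"s1"}, ["S1", "S2", "S3"])
        assert ap == 0.0
        assert select_supportive_snps(gwas, ap, ["S1", "S2", "S3"]) == {"s1", "s2"}

    def test_empty_key_set_raises(self, cascade_fixture):
        gwas, _, _ = cascade_fixture
        with pytest.raises(ValueError, match="no key"):
            compute_ap(gwas, set(), ["S1"])

    def test_supportive_comparator_unrounded(self):
        gwas = _grid({
            "a": [0.9, 0.01, 0.01, 0.01],  # count 3
            "b": [0.9, 0.01, 0.01, 0.9],   # count 2
        })
        supp = ["S1", "S2", "S3"]
        assert select_supportive_snps(gwas, 3.0, supp) == {"a"}
        assert select_supportive_snps(gwas, 3.4, supp) == set()  # 3 < 3.4
        assert select_supportive_snps(gwas, 3.0, supp, comparator=">") == set()
        assert select_supportive_snps(gwas, 2.0, supp, comparator=">") == {"a"}

    def test_supportive_selection_matches_brute_force(self, rng):
        p = pd.DataFrame(rng.uniform(0, 0.2, (25, 4)), columns=list("KABC"),
                         index=[f"s{i}" for i in range(25)])
        gwas = GwasTable(effects=p * 0.0, pvalues=p)
        ap = 1.7
        got = select_supportive_snps(gwas, ap, ["A", "B", "C"], 0.1)
        expected = {
            s for s in p.index if (p.loc[s, ["A", "B", "C"]] <= 0.1).sum() >= ap
        }
        assert got == expected


class TestGeneMapping:
    def _inputs(self):
        snp_map = SnpMap(pd.DataFrame({
            "snp": ["in_gene", "at_2500", "at_2501"],
            "chrom": "1",
            "pos": [5000, 7500 + 2500, 7500 + 2501],
        }))
        genes = GeneAnnotationSet(pd.DataFrame(
            {"gene": ["g"], "chrom": "1", "start": [4000], "end": [7500]}
        ))
        return snp_map, genes

    def test_distance_boundary(self):
        snp_map, genes = self._inputs()
        got = map_snps_to_genes({"in_gene", "at_2500", "at_2501"}, snp_map, genes)
        assert got == {"in_gene": "g", "at_2500": "g"}

    def test_matches_exhaustive_nearest_gene_scan(self, rng):
        n_snps, n_genes = 100, 10
        snp_map = SnpMap(pd.DataFrame({
            "snp": [f"s{i}" for i in range(n_snps)],
            "chrom": "1",
            "pos": rng.integers(1, 200_000, n_snps),
        }))
        starts = np.sort(rng.integers(1, 180_000, n_genes))
        genes = GeneAnnotationSet(pd.DataFrame({
            "gene": [f"g{i}" for i in range(n_genes)],
            "chrom": "1",
            "start": starts,
            "end": starts + 3000,
        }))
        got = map_snps_to_genes(set(snp_map.snps), snp_map, genes, max_dist=2500)
        for _, row in snp_map.table.iterrows():
            dists = {}
            for _, g in genes.table.iterrows():
                if g["start"] <= row["pos"] <= g["end"]:
                    d = 0
                else:
                    d = min(abs(row["pos"] - g["start"]), abs(row["pos"] - g["end"]))
                dists[g["gene"]] = d
            best = min(sorted(dists), key=lambda k: dists[k])
            if dists[best] <= 2500:
                assert got[row["snp"]] in {g for g, d in dists.items() if d == dists[best]}
            else:
                assert row["snp"] not in got


class TestOneGeneOneSnp:
    def test_association_count_wins(self, cascade_fixture):
        gwas, snp_map, _ = cascade_fixture
        out = resolve_one_gene_one_snp({"gA": ["s1", "s2"]}, gwas, snp_map)
        assert out == {"gA": "s1"}  # 3 hits beats 2

    def test_mean_p_breaks_count_tie(self):
        gwas = _grid({
            "a": [0.01, 0.02, 0.9, 0.9],
            "b": [0.01, 0.04, 0.9, 0.9],  # same count, higher mean p
        })
        assert resolve_one_gene_one_snp({"g": ["b", "a"]}, gwas) == {"g": "a"}

    def test_position_then_id_break_remaining_ties(self):
        gwas = _grid({"a": [0.01, 0.9, 0.9, 0.9], "b": [0.01, 0.9, 0.9, 0.9]})
        gwas.pvalues.loc["b"] = gwas.pvalues.loc["a"]
        gwas.effects.loc["b"] = gwas.effects.loc["a"]
        snp_map = SnpMap(pd.DataFrame(
            {"snp": ["a", "b"], "chrom": "1", "pos": [500, 100]}
        ))
        assert resolve_one_gene_one_snp({"g": ["a", "b"]}, gwas, snp_map) == {"g": "b"}
        assert resolve_one_gene_one_snp({"g": ["a", "b"]}, gwas) == {"g": "a"}

    def test_matches_exhaustive_comparator(self, rng):
        snps = [f"s{i}" for i in range(12)]
        p = pd.DataFrame(rng.uniform(0, 0.2, (12, 4)), index=snps, columns=list("KABC"))
        gwas = GwasTable(effects=p * 0.0, pvalues=p)
        pos = pd.Series(rng.permutation(12) + 1, index=snps)
        snp_map = SnpMap(pd.DataFrame({"snp": snps, "chrom": "1", "pos": pos.to_numpy()}))
        got = resolve_one_gene_one_snp({"g": snps}, gwas, snp_map)["g"]
        best = sorted(
            snps,
            key=lambda s: (
                -(p.loc[s] <= 0.05).sum(),
                p.loc[s].mean(),
                pos[s],
                s,
            ),
        )[0]
        assert got == best


class TestInjection:
    def _extra(self, p=0.01):
        return pd.DataFrame([{
            "snp": "inj1", "gene": "gZ",
            "effect_K": 5.0, "effect_S1": 5.0, "effect_S2": 5.0, "effect_S3": 5.0,
            "p_K": p, "p_S1": p, "p_S2": p, "p_S3": p,
        }])

    def test_injected_rows_enter_standardization(self, cascade_fixture):
        gwas, snp_map, genes = cascade_fixture
        augmented, gene_map = inject_custom_snps(gwas, self._extra())
        assert len(augmented.effects) == 9 and gene_map == {"inj1": "gZ"}
        std = standardize_effects(augmented)
        manual = (augmented.effects - augmented.effects.mean()) / augmented.effects.std(ddof=1)
        np.testing.assert_allclose(std.to_numpy(), manual.to_numpy(), atol=1e-12)

    def test_injected_gene_reaches_final_awm(self, cascade_fixture):
        gwas, snp_map, genes = cascade_fixture
        awm = build_awm(gwas, snp_map, genes, ["K"], ["S1", "S2", "S3"],
                        inject=self._extra())
        assert "gZ" in awm.genes
        assert awm.gene_info.loc["gZ", "provenance"] == "injected"

    def test_injected_snp_failing_selection_absent(self, cascade_fixture):
        gwas, snp_map, genes = cascade_fixture
        awm = build_awm(gwas, snp_map, genes, ["K"], ["S1", "S2", "S3"],
                        inject=self._extra(p=0.9))
        assert "gZ" not in awm.genes

    def test_injection_order_irrelevant(self, cascade_fixture):
        gwas, snp_map, genes = cascade_fixture
        extra = pd.concat([self._extra(), self._extra(p=0.02).assign(snp="inj2", gene="gY")])
        a = build_awm(gwas, snp_map, genes, ["K"], ["S1", "S2", "S3"], inject=extra)
        b = build_awm(gwas, snp_map, genes, ["K"], ["S1", "S2", "S3"],
                      inject=extra.iloc[::-1])
        pd.testing.assert_frame_equal(a.values, b.values)
        pd.testing.assert_frame_equal(a.gene_info, b.gene_info)

    def test_missing_trait_columns_rejected(self, cascade_fixture):
        gwas, _, _ = cascade_fixture
        with pytest.raises(ValueError, match="p_S3"):
            inject_custom_snps(gwas, self._extra().drop(columns=["p_S3"]))


class TestTraitCorrelation:
    def _traits(self, vals):
        df = pd.DataFrame(vals)
        roles = {c: "supportive" for c in df.columns}
        return TraitTable(df, df.iloc[:, :0], roles)

    def test_self_and_monotone_transform(self, rng):
        x = rng.standard_normal(30)
        tt = self._traits({"a": x, "b": np.exp(x)})
        corr = trait_correlation_matrix(tt)
        assert corr.loc["a", "a"] == pytest.approx(1.0)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        vals = {f"t{j}": rng.standard_normal(5) for j in range(4)}
        corr = trait_correlation_matrix(self._traits(vals))
        df = pd.DataFrame(vals)
        ranks = df.rank()
        expected = ranks.corr(method="pearson")
        np.testing.assert_allclose(corr.to_numpy(), expected.to_numpy(), atol=1e-12)

    def test_constant_trait_warns_and_is_missing(self, rng):
        tt = self._traits({"a": rng.standard_normal(10), "flat": np.ones(10)})
        with pytest.warns(UserWarning, match="flat"):
            corr = trait_correlation_matrix(tt)
        assert np.isnan(corr.loc["a", "flat"])


class TestBuildAwm:
    def test_hand_walked_cascade(self, cascade_fixture):
        gwas, snp_map, genes = cascade_fixture
        awm = build_awm(gwas, snp_map, genes, ["K"], ["S1", "S2", "S3"])
        assert awm.genes == ["gA", "gB", "gC", "gD"]  # sorted by position
        assert awm.gene_info["snp"].tolist() == ["s1", "s3", "s4", "s7"]
        assert awm.a_p == pytest.approx(1.0)
        assert awm.gene_info["provenance"].tolist() == [
            "key_selected", "supportive_selected", "supportive_selected", "key_selected",
        ]
        std = (gwas.effects - gwas.effects.mean()) / gwas.effects.std(ddof=1)
        np.testing.assert_allclose(
            awm.values.to_numpy(),
            std.loc[["s1", "s3", "s4", "s7"], ["K", "S1", "S2", "S3"]].to_numpy(),
            atol=1e-12,
        )

    def test_vacuous_threshold_admits_all_mapped_genes(self, cascade_fixture):
        gwas, snp_map, genes = cascade_fixture
        awm = build_awm(gwas, snp_map, genes, ["K"], ["S1", "S2", "S3"], p_thresh=1.0)
        assert set(awm.genes) == {"gA", "gB", "gC", "gD"}

    def test_metabolite_only_mode_changes_selection(self, cascade_fixture):
        gwas, snp_map, genes = cascade_fixture
        reduced = GwasTable(effects=gwas.effects[["S1", "S2", "S3"]],
                            pvalues=gwas.pvalues[["S1", "S2", "S3"]])
        awm = build_awm(reduced, snp_map, genes, [], ["S1", "S2", "S3"],
                        a_p_override=2.0)
        # only s1 and s3 hit >= 2 supportive traits; s7 (key-only) is gone
        assert set(awm.genes) == {"gA", "gB"}
        assert awm.traits == ["S1", "S2", "S3"]

    def test_empty_selection_raises(self, cascade_fixture):
        gwas, snp_map, genes = cascade_fixture
        with pytest.raises(ValueError):
            build_awm(gwas, snp_map, genes, ["K"], ["S1", "S2", "S3"], p_thresh=0.0)

    def test_round_ap_flag(self, cascade_fixture):
        gwas, snp_map, genes = cascade_fixture
        awm = build_awm(gwas, snp_map, genes, ["K"], ["S1", "S2", "S3"], round_ap=True)
        assert awm.a_p == 1.0  # already integral here; flag exercised

    def test_deterministic_row_order(self, cascade_fixture):
        gwas, snp_map, genes = cascade_fixture
        a = build_awm(gwas, snp_map, genes, ["K"], ["S1", "S2", "S3"])
        b = build_awm(gwas, snp_map, genes, ["K"], ["S1", "S2", "S3"])
        pd.testing.assert_frame_equal(a.values, b.values)
        info = a.gene_info.reset_index()
        sorted_info = info.sort_values(["chrom", "pos", "gene"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(info, sorted_info)
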