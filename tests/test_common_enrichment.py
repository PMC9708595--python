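"""GWAS QC, gene statistics and the competitive gene-set test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gsconverge.common_enrichment import (
    CollinearityError,
    DegenerateDesignError,
    annotate_snps,
    competitive_test,
    compute_gene_stats,
    conditional_competitive,
    gene_pvalue,
    qc_gwas,
    run_common,
)
from gsconverge.genesets import GeneSet, GeneSetCollection
from gsconverge.synthetic_data import SimConfig, gen_gene_table, gen_gwas


def _sumstats(rows):
    return pd.DataFrame(rows, columns=["SNP", "CHR", "BP", "P", "INFO", "N"])


class TestQcGwas:
    def test_info_boundary_strict(self):
        gwas = _sumstats(
            [("rs1", "chr1", 10, 0.5, 0.79, 100), ("rs2", "chr1", 20, 0.5, 0.80, 100)]
        )
        out = qc_gwas(gwas)
        assert list(out["SNP"]) == ["rs2"]

    def test_duplicates_fully_removed(self):
        gwas = _sumstats(
            [
                ("rs1", "chr1", 10, 0.5, 0.9, 100),
                ("rs1", "chr1", 10, 0.4, 0.95, 100),
                ("rs2", "chr1", 20, 0.5, 0.9, 100),
            ]
        )
        out = qc_gwas(gwas)
        assert list(out["SNP"]) == ["rs2"]

    def test_clean_input_identity(self):
        gwas = _sumstats(
            [("rs1", "chr1", 10, 0.5, 0.9, 100), ("rs2", "chr1", 20, 0.1, 1.0, 100)]
        )
        pd.testing.assert_frame_equal(qc_gwas(gwas), gwas)


class TestAnnotateSnps:
    @pytest.fixture()
    def genes(self):
        return pd.DataFrame(
            {
                "gene_id": ["gA", "gB"],
                "chrom": ["chr1", "chr1"],
                "start": [100, 150],
                "stop": [200, 300],
                "pli": [0.5, 0.5],
            }
        )

    def test_boundaries_inclusive(self, genes):
        gwas = _sumstats(
            [
                ("s_start", "chr1", 100, 0.5, 1.0, 10),
                ("s_stop", "chr1", 200, 0.5, 1.0, 10),
                ("s_past", "chr1", 301, 0.5, 1.0, 10),
            ]
        )
        out = annotate_snps(gwas, genes)
        in_gA = set(out.loc[out["gene_id"] == "gA", "SNP"])
        assert {"s_start", "s_stop"} <= in_gA
        assert "s_past" not in set(out["SNP"])

    def test_overlapping_genes_get_both(self, genes):
        gwas = _sumstats([("s_mid", "chr1", 175, 0.5, 1.0, 10)])
        out = annotate_snps(gwas, genes)
        assert set(out["gene_id"]) == {"gA", "gB"}

    def test_no_window_excludes_adjacent(self, genes):
        gwas = _sumstats([("s_next", "chr1", 201, 0.5, 1.0, 10)])
        out = annotate_snps(gwas, genes)
        assert set(out["gene_id"]) == {"gB"}  # inside gB only, past gA stop


class TestGenePvalue:
    def test_single_snp_identity(self):
        gs = gene_pvalue(np.array([0.01]), np.array([[1.0]]))
        assert gs.p_gene == pytest.approx(0.01, rel=1e-10)
        assert gs.z == pytest.approx(stats.norm.isf(0.01), rel=1e-9)

    def test_two_independent_snps_closed_form(self):
        # chi-square of 1 per SNP: p = P(chi2_1 > 1)
        p1 = stats.chi2.sf(1.0, 1)
        gs = gene_pvalue(np.array([p1, p1]), np.eye(2))
        assert gs.T == pytest.approx(2.0, rel=1e-12)
        assert gs.p_gene == pytest.approx(np.exp(-1.0), rel=1e-10)

    def test_correlated_triple_matches_monte_carlo(self):
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        p1 = stats.chi2.sf(1.0, 1)
        gs = gene_pvalue(np.array([p1] * 3), R)
        lam = np.clip(np.linalg.eigvalsh(R), 0, None)
        rng = np.random.default_rng(42)
        draws = rng.chisquare(1, size=(1_000_000, 3)) @ lam
        mc = float((draws > 3.0).mean())
        se = np.sqrt(mc * (1 - mc) / 1_000_000)
        assert abs(gs.p_gene - mc) <= 3 * se

    def test_zero_pvalue_rejected(self):
        with pytest.raises(ValueError):
            gene_pvalue(np.array([0.0]), np.array([[1.0]]))

    def test_non_psd_rejected(self):
        R = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="semidefinite"):
            gene_pvalue(np.array([0.5, 0.5]), R)

    def test_probit_consistency_z_decreasing_in_p(self):
        ps = [0.001, 0.01, 0.1, 0.5, 0.9]
        zs = [gene_pvalue(np.array([p]), np.array([[1.0]])).z for p in ps]
        assert all(a > b for a, b in zip(zs, zs[1:]))


class TestCompetitiveTest:
    def test_constant_z_gives_zero_beta_half_p(self):
        z = pd.Series(1.0, index=[f"g{i}" for i in range(20)])
        res = competitive_test(z, {"g0", "g1", "g2"})
        assert res.beta == 0.0 and res.p == 0.5

    def test_shifted_members_recovered_within_2se(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i:04d}" for i in range(1000)]
        z = pd.Series(rng.normal(0, 1, 1000), index=genes)
        members = set(rng.choice(genes, 100, replace=False))
        z[list(members)] += 0.5
        res = competitive_test(z, members)
        assert abs(res.beta - 0.5) <= 2 * res.se

    def test_empty_or_universal_set_rejected(self):
        z = pd.Series(np.arange(5.0), index=[f"g{i}" for i in range(5)])
        with pytest.raises(DegenerateDesignError):
            competitive_test(z, set())
        with pytest.raises(DegenerateDesignError):
            competitive_test(z, set(z.index))

    def test_one_sided_p_small_for_enriched(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i:04d}" for i in range(500)]
        z = pd.Series(rng.normal(0, 1, 500), index=genes)
        members = set(genes[:50])
        z[list(members)] += 1.0
        res = competitive_test(z, members)
        assert res.p < 1e-4


class TestConditionalCompetitive:
    def test_conditioning_on_self_rejected(self):
        z = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
        members = {"g0", "g1", "g2"}
        with pytest.raises(CollinearityError):
            conditional_competitive(z, members, {"same": set(members)})

    def test_disjoint_null_conditioning_leaves_beta(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i:04d}" for i in range(1000)]
        deltas = []
        for _ in range(20):
            z = pd.Series(rng.normal(0, 1, 1000), index=genes)
            members = set(genes[:100])
            null_cond = set(genes[500:600])
            z[list(members)] += 0.4
            r0 = competitive_test(z, members)
            r1 = conditional_competitive(z, members, {"null": null_cond})
            deltas.append(r1.beta - r0.beta)
            assert abs(r1.beta - r0.beta) <= 2 * r0.se
        assert abs(np.mean(deltas)) <= 2 * np.std(deltas) / np.sqrt(len(deltas)) + 0.02

    def test_attenuation_when_signal_from_conditioning_set(self):
        # signal lives in PI; the intersection subset has no extra effect
        rng = np.random.default_rng(10)
        genes = [f"g{i:04d}" for i in range(2000)]
        pi = set(genes[:400])
        cell = set(genes[200:600])
        inter = pi & cell
        z = pd.Series(rng.normal(0, 1, 2000), index=genes)
        z[list(pi)] += 0.6
        r0 = competitive_test(z, inter)
        r1 = conditional_competitive(z, inter, {"PI": pi})
        assert r0.beta > 0.3
        assert r1.beta < r0.beta
        assert abs(r1.beta) <= 2.5 * r1.se


@pytest.fixture(scope="module")
def pipeline():
    cfg = SimConfig(
        n_genes=400, tau2_null=0.0, tau2_enriched=2e-5, seed=21,
        enriched_set_names=("hot",),
    )
    genes = gen_gene_table(cfg)
    hot = GeneSet("hot", "synaptic", tuple(genes["gene_id"].iloc[:80]))
    cold = GeneSet("cold", "synaptic", tuple(genes["gene_id"].iloc[100:180]))
    coll = GeneSetCollection()
    coll.add(hot)
    coll.add(cold)
    gwas, ld = gen_gwas(genes, cfg, [hot])
    return cfg, genes, coll, gwas, ld


class TestRunCommon:
    def test_one_primary_row_per_set_and_signal_detected(self, pipeline):
        cfg, genes, coll, gwas, ld = pipeline
        res = run_common(gwas, ld, genes, coll)
        prim = res[res["conditioned_on"] == ""]
        assert len(prim) == 2
        hot_row = prim[prim["set_name"] == "hot"].iloc[0]
        cold_row = prim[prim["set_name"] == "cold"].iloc[0]
        assert hot_row["p"] < 0.01
        assert hot_row["beta"] > cold_row["beta"]

    def test_rerun_identical(self, pipeline):
        cfg, genes, coll, gwas, ld = pipeline
        r1 = run_common(gwas, ld, genes, coll)
        r2 = run_common(gwas, ld, genes, coll)
        pd.testing.assert_frame_equal(r1, r2)

    def test_empty_collection_empty_table(self, pipeline):
        cfg, genes, coll, gwas, ld = pipeline
        res = run_common(gwas, ld, genes, GeneSetCollection())
        assert len(res) == 0

    def test_small_sets_skipped_not_dropped(self, pipeline):
        cfg, genes, coll, gwas, ld = pipeline
        tiny = GeneSetCollection()
        tiny.add(GeneSet("tiny", "synaptic", tuple(genes["gene_id"].iloc[:3])))
        res = run_common(gwas, ld, genes, tiny)
        assert list(res["status"]) == ["skipped_small"]

    def test_null_gene_pvalues_uniform(self):
        cfg = SimConfig(n_genes=5000, ld_block_size=4, ld_rho=0.5,
                        tau2_null=0.0, tau2_enriched=0.0, seed=22)
        genes = gen_gene_table(cfg)
        gwas, ld = gen_gwas(genes, cfg, None)
        stats_df = compute_gene_stats(qc_gwas(gwas), ld, genes)
        assert len(stats_df) == 5000
        ks = stats.kstest(stats_df["p_gene"], "uniform")
        assert ks.pvalue > 0.01
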