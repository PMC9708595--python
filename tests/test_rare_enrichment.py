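"""Variant classification, MAD sample QC and the logistic burden regression."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsconverge.genesets import GeneSet, GeneSetCollection
from gsconverge.rare_enrichment import (
    DegenerateBurdenError,
    burden_regression,
    burden_score,
    class_mask,
    classify_variants,
    run_rare,
    sample_qc_mad,
)
from gsconverge.synthetic_data import ExomeCohort, SimConfig, gen_exome_cohort


def _variants(rows):
    return pd.DataFrame(
        rows, columns=["variant_id", "gene_id", "consequence", "ac_sample", "ac_ref"]
    )


class TestClassifyVariants:
    PANEL = 188_023

    def test_single_allele_is_singleton(self):
        v = classify_variants(_variants([("v1", "g1", "PTV", 1, 0)]), self.PANEL)
        assert bool(v["singleton"][0]) and bool(v["rare_incl"][0])
        assert not bool(v["rare_excl"][0])

    def test_two_alleles_rare_but_not_singleton(self):
        v = classify_variants(_variants([("v1", "g1", "PTV", 1, 1)]), self.PANEL)
        assert not bool(v["singleton"][0])
        assert bool(v["rare_incl"][0]) and bool(v["rare_excl"][0])
        assert v["af"][0] == pytest.approx(2 / (2 * self.PANEL))

    def test_common_variant_in_no_rare_class(self):
        ac = int(0.005 * 2 * self.PANEL)
        v = classify_variants(_variants([("v1", "g1", "PTV", 2, ac - 2)]), self.PANEL)
        assert not (v["singleton"][0] or v["rare_incl"][0] or v["rare_excl"][0])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            classify_variants(_variants([("v1", "g1", "PTV", -1, 0)]), self.PANEL)

    @settings(max_examples=100, deadline=None)
    @given(ac_sample=st.integers(0, 500), ac_ref=st.integers(0, 500))
    def test_class_nesting(self, ac_sample, ac_ref):
        v = classify_variants(
            _variants([("v", "g", "PTV", ac_sample, ac_ref)]), self.PANEL
        )
        singleton, incl, excl = bool(v["singleton"][0]), bool(v["rare_incl"][0]), bool(v["rare_excl"][0])
        if singleton:
            assert incl and not excl
        assert incl == (excl or (singleton and incl))

    def test_consequence_crossing(self):
        v = classify_variants(
            _variants([("v1", "g1", "PTV", 1, 0), ("v2", "g1", "synonymous", 1, 0)]),
            self.PANEL,
        )
        assert list(class_mask(v, "urv_ptv")) == [True, False]
        assert list(class_mask(v, "urv_syn")) == [False, True]


class TestSampleQcMad:
    def test_hand_computed_example(self):
        counts = pd.Series([7, 8, 8, 9, 9, 10, 50])
        keep = sample_qc_mad(counts, k=4)
        # median 9, MAD 1 -> keep |x-9| <= 4: only the 50 is excluded
        assert list(keep) == [True] * 6 + [False]

    def test_all_equal_nobody_excluded(self):
        keep = sample_qc_mad(pd.Series([5, 5, 5, 5]), k=4)
        assert keep.all()

    def test_zero_mad_excludes_any_deviation(self):
        keep = sample_qc_mad(pd.Series([5, 5, 5, 5, 6]), k=4)
        assert list(keep) == [True] * 4 + [False]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sample_qc_mad(pd.Series([], dtype=float))


def _toy_cohort():
    individuals = pd.DataFrame(
        {"iid": ["a", "b", "c"], "case": [1, 0, 1], "sex": [0, 1, 0]}
    )
    for j in range(10):
        individuals[f"PC{j+1}"] = 0.0
    variants = _variants(
        [
            ("v1", "g1", "PTV", 2, 0),
            ("v2", "g2", "PTV", 1, 0),
            ("v3", "g3", "PTV", 1, 0),
            ("v4", "g1", "synonymous", 1, 0),
        ]
    )
    carriers = pd.DataFrame(
        {
            "variant_id": ["v1", "v1", "v2", "v3", "v4"],
            "iid": ["a", "b", "a", "b", "c"],
            "n_alleles": [1, 1, 1, 1, 1],
        }
    )
    return ExomeCohort(individuals, variants, carriers, 188_023)


class TestBurdenScore:
    def test_set_and_exome_wide_counts(self):
        cohort = _toy_cohort()
        classified = classify_variants(cohort.variants, cohort.panel_total_n)
        in_set = burden_score(cohort, {"g1", "g2"}, classified, "rare_ptv")
        exome = burden_score(cohort, None, classified, "rare_ptv")
        assert list(in_set) == [2, 1, 0]  # a: v1+v2, b: v1, c: none
        assert list(exome) == [2, 2, 0]

    def test_empty_set_all_zero(self):
        cohort = _toy_cohort()
        classified = classify_variants(cohort.variants, cohort.panel_total_n)
        assert burden_score(cohort, set(), classified, "rare_ptv").sum() == 0

    def test_partition_conservation(self):
        cohort = _toy_cohort()
        classified = classify_variants(cohort.variants, cohort.panel_total_n)
        exome = burden_score(cohort, None, classified, "rare_ptv")
        part = sum(
            burden_score(cohort, {g}, classified, "rare_ptv")
            for g in ["g1", "g2", "g3"]
        )
        assert list(part) == list(exome)


class TestBurdenRegression:
    def test_2x2_closed_form_log_odds_ratio(self):
        # 30/1000 case carriers vs 10/1000 control carriers, binary burden
        n = 1000
        individuals = pd.DataFrame(
            {
                "iid": [f"i{j}" for j in range(2 * n)],
                "case": [1] * n + [0] * n,
                "sex": [0] * (2 * n),
            }
        )
        for j in range(10):
            individuals[f"PC{j+1}"] = 0.0
        burden = pd.Series(
            [1] * 30 + [0] * 970 + [1] * 10 + [0] * 990,
            index=individuals["iid"],
        )
        res = burden_regression(individuals, burden, "urv_ptv")
        expected = np.log((30 / 970) / (10 / 990))
        assert res.beta == pytest.approx(expected, abs=1e-6)

    def test_constant_burden_rejected(self):
        individuals = _toy_cohort().individuals
        burden = pd.Series(0, index=individuals["iid"])
        with pytest.raises(DegenerateBurdenError):
            burden_regression(individuals, burden, "urv_ptv")

    def test_single_class_outcome_rejected(self):
        individuals = _toy_cohort().individuals.assign(case=1)
        burden = pd.Series([1, 0, 0], index=individuals["iid"])
        with pytest.raises(DegenerateBurdenError):
            burden_regression(individuals, burden, "urv_ptv")

    def test_matches_independent_irls_oracle(self):
        rng = np.random.default_rng(3)
        n = 400
        individuals = pd.DataFrame(
            {
                "iid": [f"i{j}" for j in range(n)],
                "case": rng.integers(0, 2, n),
                "sex": rng.integers(0, 2, n),
            }
        )
        for j in range(10):
            individuals[f"PC{j+1}"] = rng.normal(size=n)
        burden = pd.Series(rng.poisson(0.5, n), index=individuals["iid"])
        res = burden_regression(individuals, burden, "urv_ptv")

        # independent IRLS implementation
        X = np.column_stack(
            [
                np.ones(n),
                burden.to_numpy(float),
                individuals["sex"].to_numpy(float),
                individuals[[f"PC{j+1}" for j in range(10)]].to_numpy(float),
            ]
        )
        y = individuals["case"].to_numpy(float)
        beta = np.zeros(X.shape[1])
        for _ in range(50):
            eta = X @ beta
            p = 1 / (1 + np.exp(-eta))
            W = p * (1 - p)
            z = eta + (y - p) / W
            beta_new = np.linalg.solve((X.T * W) @ X, (X.T * W) @ z)
            if np.max(np.abs(beta_new - beta)) < 1e-12:
                beta = beta_new
                break
            beta = beta_new
        se = np.sqrt(np.diag(np.linalg.inv((X.T * (p * (1 - p))) @ X)))
        assert res.beta == pytest.approx(beta[1], abs=1e-6)
        assert res.se == pytest.approx(se[1], abs=1e-6)

    def test_separation_falls_back_to_firth(self):
        n = 40
        individuals = pd.DataFrame(
            {
                "iid": [f"i{j}" for j in range(n)],
                "case": [1] * 20 + [0] * 20,
                "sex": [0] * n,
            }
        )
        for j in range(10):
            individuals[f"PC{j+1}"] = 0.0
        burden = pd.Series([1] * 20 + [0] * 20, index=individuals["iid"])  # perfect separation
        res = burden_regression(individuals, burden, "urv_ptv")
        assert res.status == "firth"
        assert np.isfinite(res.beta) and np.isfinite(res.se)


class TestNullAndRecovery:
    def test_null_burden_within_2se_of_zero(self, small_genes, small_sim_config):
        cfg = replace(small_sim_config, burden_logor=0.0, seed=31)
        cohort = gen_exome_cohort(small_genes, cfg, None)
        classified = classify_variants(cohort.variants, cohort.panel_total_n)
        members = set(small_genes["gene_id"].iloc[:100])
        burden = burden_score(cohort, members, classified, "rare_ptv")
        res = burden_regression(cohort.individuals, burden, "rare_ptv")
        assert abs(res.beta) <= 2 * res.se

    def test_synonymous_null_in_planted_cohort(self, small_genes, small_sim_config):
        causal = GeneSet("causal", "synaptic", tuple(small_genes["gene_id"].iloc[:100]))
        cfg = replace(small_sim_config, burden_logor=0.5,
                      enriched_set_names=("causal",), seed=32)
        cohort = gen_exome_cohort(small_genes, cfg, [causal])
        classified = classify_variants(cohort.variants, cohort.panel_total_n)
        syn = burden_score(cohort, causal.member_set(), classified, "rare_syn")
        res = burden_regression(cohort.individuals, syn, "rare_syn")
        assert abs(res.beta) <= 2 * res.se


def _planted_run():
    cfg = SimConfig(
        n_genes=300, n_cases=400, n_controls=400, mu_ptv=3e-3, mu_syn=1.5e-2,
        burden_logor=0.4, enriched_set_names=("hot",), seed=33,
    )
    from gsconverge.synthetic_data import gen_gene_table

    genes = gen_gene_table(cfg)
    hot = GeneSet("hot", "synaptic", tuple(genes["gene_id"].iloc[:60]))
    cold = GeneSet("cold", "synaptic", tuple(genes["gene_id"].iloc[100:160]))
    coll = GeneSetCollection()
    coll.add(hot)
    coll.add(cold)
    cohort = gen_exome_cohort(genes, cfg, [hot])
    return run_rare(cohort, coll, classes=("urv_ptv", "urv_syn", "rare_ptv", "rare_syn"))


@pytest.fixture(scope="module")
def result():
    return _planted_run()


class TestRunRare:
    def test_one_row_per_set_per_class(self, result):
        prim = result[result["conditioned_on"] == ""]
        assert len(prim) == 2 * 4
        assert set(prim["variant_class"]) == {"urv_ptv", "urv_syn", "rare_ptv", "rare_syn"}

    def test_planted_set_beats_null_set(self, result):
        prim = result[(result["conditioned_on"] == "") & (result["variant_class"] == "rare_ptv")]
        hot = prim[prim["set_name"] == "hot"].iloc[0]
        cold = prim[prim["set_name"] == "cold"].iloc[0]
        assert hot["beta"] > cold["beta"]
        assert hot["p"] < 0.05

    def test_empty_cohort_rejected(self):
        empty = ExomeCohort(
            pd.DataFrame(columns=["iid", "case", "sex"]),
            _variants([]),
            pd.DataFrame(columns=["variant_id", "iid", "n_alleles"]),
            1000,
        )
        coll = GeneSetCollection()
        coll.add(GeneSet("s", "synaptic", ("g1",) * 1))
        with pytest.raises(ValueError):
            run_rare(empty, coll)

    def test_rerun_identical(self, result):
        res2 = _planted_run()
        pd.testing.assert_frame_equal(result.reset_index(drop=True), res2.reset_index(drop=True))
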