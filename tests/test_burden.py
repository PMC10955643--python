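"""Exhaustive-subset gene burden: oracle equivalence and combination rules."""

import numpy as np
import pandas as pd
import pytest

from xassoc.burden import (
    combine_subset_meta,
    eligible_genes,
    run_burden,
    subset_burden,
)
from xassoc.errors import ConfigurationError, DesignError
from xassoc.simulate import SimulationConfig, simulate_cohort_pair
from xassoc.association import run_association

from .oracles import brute_force_burden, chi2_4_sf


def _result_rows(make_assoc_table, rows):
    return make_assoc_table(rows)


class TestEligibleGenes:
    def test_threshold_count(self, make_assoc_table):
        table = make_assoc_table(
            [
                ("v1", "G1", 10, 90, 2, 98, 0.01, "case"),
                ("v2", "G1", 9, 91, 2, 98, 0.04, "case"),
                ("v3", "G1", 5, 95, 4, 96, 0.2, "case"),
                ("v4", "G2", 10, 90, 2, 98, 0.03, "case"),
            ]
        )
        eligible = eligible_genes(table, alpha=0.05)
        assert set(eligible) == {"G1"}
        assert len(eligible["G1"]) == 2

    def test_single_significant_variant_not_eligible(self, make_assoc_table):
        table = make_assoc_table([("v1", "G1", 10, 90, 2, 98, 0.01, "case")])
        assert eligible_genes(table, alpha=0.05) == {}

    def test_simulated_rich_gene_recovered_with_all_variants(self):
        """Recount oracle: the planted 4-variant gene appears with 4 entries."""
        cfg = SimulationConfig(
            n_variants=200, n_genes=20, n_planted_case=0, n_planted_ctrl=0,
            n_variant_rich_genes=1, variants_per_rich_gene=4,
            planted_or=8.0, nocall_rate=0.0, seed=17,
        )
        disc, _, truth = simulate_cohort_pair(cfg)
        gene_map = dict(zip(truth["variant_id"], truth["gene"]))
        results, _ = run_association(disc, gene_map=gene_map)
        eligible = eligible_genes(results, alpha=0.05)
        rich_gene = truth.loc[truth["status"] != "null", "gene"].iloc[0]
        assert rich_gene in eligible
        planted_ids = set(truth.loc[truth["status"] != "null", "variant_id"])
        got = set(eligible[rich_gene]["variant_id"])
        # recount directly from the association output
        expected = set(
            results[(results["gene"] == rich_gene) & (results["p"] < 0.05)]["variant_id"]
        )
        assert got == expected
        assert planted_ids <= got


class TestSubsetBurden:
    def test_subset_count_identity(self, make_assoc_table):
        """k variants -> 2^k - 1 subsets; checked through the Bonferroni factor."""
        table = make_assoc_table(
            [
                ("v1", "G", 20, 80, 2, 98, 1e-4, "case"),
                ("v2", "G", 18, 82, 3, 97, 1e-3, "case"),
            ]
        )
        res = subset_burden(table)
        oracle = brute_force_burden(table.to_dict("records"))
        # 3 subsets for k=2: meta_p is the best subset p times 3
        assert res.meta_p == pytest.approx(oracle["meta_p"], abs=1e-12)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_brute_force_oracle_on_seeded_genes(self, k):
        rng = np.random.default_rng(100 + k)
        for _ in range(10):
            rows = []
            for i in range(k):
                direction = rng.choice(["case", "control"])
                a = int(rng.integers(0, 30))
                c = int(rng.integers(0, 30))
                rows.append(
                    {
                        "variant_id": f"v{i}",
                        "gene": "G",
                        "case_alt": a, "case_ref": 100 - a,
                        "ctrl_alt": c, "ctrl_ref": 100 - c,
                        "p": 0.01, "direction": direction,
                        "af_case": a / 100, "af_ctrl": c / 100,
                    }
                )
            res = subset_burden(pd.DataFrame(rows))
            oracle = brute_force_burden(rows)
            assert res.meta_p == pytest.approx(oracle["meta_p"], abs=1e-12)
            assert res.subset_case_meta_p == pytest.approx(
                oracle["subset_case_meta_p"], abs=1e-12
            )
            assert res.subset_control_meta_p == pytest.approx(
                oracle["subset_control_meta_p"], abs=1e-12
            )
            assert res.subset_meta_p == pytest.approx(
                oracle["subset_meta_p"], abs=1e-12
            )
            assert res.best_case_subset == oracle["best_case_subset"]
            assert res.best_control_subset == oracle["best_control_subset"]

    def test_variant_order_permutation_invariant(self, make_assoc_table):
        rows = [
            ("v1", "G", 20, 80, 2, 98, 1e-4, "case"),
            ("v2", "G", 3, 97, 15, 85, 1e-2, "control"),
            ("v3", "G", 18, 82, 3, 97, 1e-3, "case"),
        ]
        res1 = subset_burden(make_assoc_table(rows))
        res2 = subset_burden(make_assoc_table(rows[::-1]))
        for attr in ("meta_p", "subset_case_meta_p", "subset_control_meta_p", "subset_meta_p"):
            assert getattr(res1, attr) == getattr(res2, attr)

    def test_all_case_enriched_gene_has_control_meta_p_one(self, make_assoc_table):
        table = make_assoc_table(
            [
                ("v1", "G", 20, 80, 2, 98, 1e-4, "case"),
                ("v2", "G", 18, 82, 3, 97, 1e-3, "case"),
            ]
        )
        res = subset_burden(table)
        assert res.subset_control_meta_p == 1.0
        assert res.best_control_subset == []

    def test_meta_p_bounded_by_bonferroni_best_single(self, make_assoc_table):
        table = make_assoc_table(
            [
                ("v1", "G", 20, 80, 2, 98, 1e-4, "case"),
                ("v2", "G", 5, 95, 4, 96, 0.04, "case"),
                ("v3", "G", 3, 97, 15, 85, 0.01, "control"),
            ]
        )
        res = subset_burden(table)
        from xassoc.association import AlleleTable, exact_allelic_test

        singles = [
            exact_allelic_test(AlleleTable(r.case_alt, r.case_ref, r.ctrl_alt, r.ctrl_ref))[0]
            for r in table.itertuples()
        ]
        assert res.meta_p <= min(singles) * 7 + 1e-12
        assert res.meta_p <= 1.0

    def test_k_bounds_enforced(self, make_assoc_table):
        one = make_assoc_table([("v1", "G", 20, 80, 2, 98, 1e-4, "case")])
        with pytest.raises(DesignError):
            subset_burden(one)
        many = make_assoc_table(
            [(f"v{i}", "G", 10, 90, 2, 98, 0.01, "case") for i in range(13)]
        )
        with pytest.raises(ConfigurationError, match="k_max"):
            subset_burden(many)


class TestCombineSubsetMeta:
    def test_boundary_both_one(self):
        assert combine_subset_meta(1.0, 1.0) == 1.0

    def test_monotone_decreasing_in_each_argument(self):
        assert combine_subset_meta(0.01, 0.5) < combine_subset_meta(0.05, 0.5)
        assert combine_subset_meta(0.5, 0.01) < combine_subset_meta(0.5, 0.05)

    def test_symmetric(self):
        assert combine_subset_meta(0.01, 0.3) == combine_subset_meta(0.3, 0.01)

    def test_matches_closed_form_chi2_survival(self):
        x = -2 * (np.log(0.01) + np.log(0.04))
        assert combine_subset_meta(0.01, 0.04) == pytest.approx(chi2_4_sf(x), rel=1e-12)

    def test_zero_input_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            p = combine_subset_meta(0.0, 0.5)
        assert 0.0 < p < 1.0


class TestRunBurden:
    def test_null_simulation_subset_meta_is_conservative_without_screening(self):
        """Bonferroni conservativeness on pure-null genes.

        Applied to unscreened variants the subset meta-p rejects well below
        nominal. (Applied after the p < 0.05 variant screen it is anti-
        conservative by construction — the screening selects the inputs —
        which is why gene findings are validated across cohorts rather than
        trusted from one cohort's burden p alone.)
        """
        cfg = SimulationConfig(
            n_variants=2000, n_genes=500, n_planted_case=0, n_planted_ctrl=0,
            n_variant_rich_genes=0, seed=29,
        )
        disc, _, truth = simulate_cohort_pair(cfg)
        gene_map = dict(zip(truth["variant_id"], truth["gene"]))
        results, _ = run_association(disc, gene_map=gene_map)
        hits, n = 0, 0
        for _, grp in results.groupby("gene"):
            g = grp.sort_values("variant_id").head(4)
            if len(g) < 2:
                continue
            n += 1
            hits += subset_burden(g).subset_meta_p < 0.05
        frac = hits / n
        se = np.sqrt(0.05 * 0.95 / n)
        assert n >= 400
        assert frac <= 0.05 + 3 * se

    def test_oversized_gene_reported_unprocessed(self, make_assoc_table):
        rows = [(f"v{i:02d}", "G", 30, 70, 2, 98, 1e-4, "case") for i in range(5)]
        table = make_assoc_table(rows)
        out = run_burden(table, k_max=3)
        assert len(out) == 1
        assert not out.loc[0, "processed"]
        assert np.isnan(out.loc[0, "meta_p"])
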