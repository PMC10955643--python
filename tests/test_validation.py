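"""Cross-cohort validation rules, IUT combination and gene-set enrichment."""

import numpy as np
import pandas as pd
import pytest

from xassoc.errors import InputError, PipelineOrderError
from xassoc.simulate import SimulationConfig, simulate_cohort_pair
from xassoc.association import run_association
from xassoc.burden import run_burden
from xassoc.validation import (
    hypergeom_enrichment,
    iut_combine,
    validate_genes,
    validate_variants,
)

from .oracles import hypergeom_tail


class TestIutCombine:
    def test_max_by_definition(self):
        assert iut_combine(0.01, 0.04) == 0.04

    def test_idempotent(self):
        assert iut_combine(0.3, 0.3) == 0.3

    def test_significance_iff_both_components_significant(self):
        """Property sweep: combined < alpha <=> both inputs < alpha."""
        rng = np.random.default_rng(0)
        alpha = 0.05
        pairs = rng.random((10_000, 2)) * 0.2
        for p1, p2 in pairs:
            assert (iut_combine(p1, p2) < alpha) == (p1 < alpha and p2 < alpha)

    def test_rejects_out_of_range(self):
        with pytest.raises(InputError):
            iut_combine(-0.1, 0.5)


def _assoc_pair(make_assoc_table, disc_rows, val_rows):
    return make_assoc_table(disc_rows), make_assoc_table(val_rows)


class TestValidateVariants:
    def test_coherent_significant_variant_validates(self, make_assoc_table):
        disc, val = _assoc_pair(
            make_assoc_table,
            [("v1", "G1", 10, 90, 2, 98, 0.01, "case")],
            [("v1", "G1", 12, 120, 3, 163, 0.03, "case")],
        )
        validated, discordant = validate_variants(disc, val)
        assert list(validated["variant_id"]) == ["v1"]
        assert validated.loc[0, "combined_p"] == 0.03
        assert len(discordant) == 0

    def test_discordant_direction_excluded_and_reported(self, make_assoc_table):
        disc, val = _assoc_pair(
            make_assoc_table,
            [("v1", "G1", 10, 90, 2, 98, 0.01, "case")],
            [("v1", "G1", 3, 129, 12, 154, 0.03, "control")],
        )
        validated, discordant = validate_variants(disc, val)
        assert len(validated) == 0
        assert list(discordant["variant_id"]) == ["v1"]

    def test_significant_in_one_cohort_only_not_validated(self, make_assoc_table):
        disc, val = _assoc_pair(
            make_assoc_table,
            [("v1", "G1", 10, 90, 2, 98, 0.01, "case")],
            [("v1", "G1", 6, 126, 5, 161, 0.4, "case")],
        )
        validated, _ = validate_variants(disc, val)
        assert len(validated) == 0

    def test_symmetric_in_cohort_labelling(self, make_assoc_table):
        disc, val = _assoc_pair(
            make_assoc_table,
            [
                ("v1", "G1", 10, 90, 2, 98, 0.01, "case"),
                ("v2", "G2", 2, 98, 11, 89, 0.02, "control"),
            ],
            [
                ("v1", "G1", 12, 120, 3, 163, 0.03, "case"),
                ("v2", "G2", 3, 129, 14, 152, 0.01, "control"),
            ],
        )
        v1, _ = validate_variants(disc, val)
        v2, _ = validate_variants(val, disc)
        assert list(v1["variant_id"]) == list(v2["variant_id"])
        np.testing.assert_allclose(v1["combined_p"], v2["combined_p"])

    def test_alpha_monotonicity(self, make_assoc_table):
        rng = np.random.default_rng(4)
        rows_d, rows_v = [], []
        for i in range(60):
            pd_, pv_ = rng.random() * 0.15, rng.random() * 0.15
            rows_d.append((f"v{i}", "G", 10, 90, 2, 98, pd_, "case"))
            rows_v.append((f"v{i}", "G", 12, 120, 3, 163, pv_, "case"))
        disc, val = _assoc_pair(make_assoc_table, rows_d, rows_v)
        sets = [
            set(validate_variants(disc, val, alpha)[0]["variant_id"])
            for alpha in (0.01, 0.05, 0.1)
        ]
        assert sets[0] <= sets[1] <= sets[2]

    def test_duplicate_identifier_rejected(self, make_assoc_table):
        disc = make_assoc_table(
            [
                ("v1", "G1", 10, 90, 2, 98, 0.01, "case"),
                ("v1", "G1", 9, 91, 2, 98, 0.02, "case"),
            ]
        )
        val = make_assoc_table([("v1", "G1", 12, 120, 3, 163, 0.03, "case")])
        with pytest.raises(InputError, match="duplicate"):
            validate_variants(disc, val)

    def test_planted_signal_recovery_against_truth(self):
        """Truth-table comparison on a seeded paired simulation."""
        cfg = SimulationConfig(
            n_variants=1000, n_genes=100, n_planted_case=8, n_planted_ctrl=8,
            n_variant_rich_genes=0, planted_or=4.0, planted_maf_ctrl=0.15,
            seed=31,
        )
        disc, val, truth = simulate_cohort_pair(cfg)
        gene_map = dict(zip(truth["variant_id"], truth["gene"]))
        res_d, _ = run_association(disc, gene_map=gene_map)
        res_v, _ = run_association(val, gene_map=gene_map)
        validated, _ = validate_variants(res_d, res_v)
        planted = set(truth.loc[truth["status"] != "null", "variant_id"])
        nulls = set(truth.loc[truth["status"] == "null", "variant_id"])
        got = set(validated["variant_id"])
        recovery = len(got & planted) / len(planted)
        false_rate = len(got & nulls) / len(nulls)
        assert recovery >= 0.5
        assert false_rate <= 0.01
        # planted direction must match the truth direction
        truth_dir = truth.set_index("variant_id")["status"]
        for _, row in validated[validated["variant_id"].isin(planted)].iterrows():
            expected = "case" if truth_dir[row["variant_id"]] == "planted_case" else "control"
            assert row["direction"] == expected


def _burden_row(gene, p_case, p_ctrl):
    return {
        "gene": gene, "n_variants": 2, "meta_p": min(p_case, p_ctrl),
        "subset_case_meta_p": p_case, "subset_control_meta_p": p_ctrl,
        "subset_meta_p": min(p_case, p_ctrl), "best_case_subset": "",
        "best_control_subset": "", "processed": True,
    }


class TestValidateGenes:
    def test_multi_variant_coherent_gene_validates(self, make_assoc_table):
        """Four case-enriched variants per cohort with small case subset meta-p."""
        disc = make_assoc_table(
            [(f"v{i}", "HG", 20, 80, 2, 98, 0.001, "case") for i in range(4)]
        )
        val = make_assoc_table(
            [(f"w{i}", "HG", 25, 107, 3, 163, 0.002, "case") for i in range(4)]
        )
        burden_d = pd.DataFrame([_burden_row("HG", 3.46e-7, 1.0)])
        burden_v = pd.DataFrame([_burden_row("HG", 1.67e-6, 1.0)])
        out = validate_genes(disc, val, burden_d, burden_v, 0.05)
        assert list(out["gene"]) == ["HG"]
        row = out.iloc[0]
        assert row["direction"] == "case"
        assert (row["n_var_disc"], row["n_var_val"]) == (4, 4)
        assert row["p_disc"] == pytest.approx(3.46e-7)

    def test_direction_flip_across_cohorts_not_validated(self, make_assoc_table):
        disc = make_assoc_table(
            [(f"v{i}", "G", 20, 80, 2, 98, 0.001, "case") for i in range(2)]
        )
        val = make_assoc_table(
            [(f"w{i}", "G", 3, 129, 20, 146, 0.002, "control") for i in range(2)]
        )
        burden_d = pd.DataFrame([_burden_row("G", 1e-4, 1.0)])
        burden_v = pd.DataFrame([_burden_row("G", 1.0, 1e-4)])
        out = validate_genes(disc, val, burden_d, burden_v, 0.05)
        assert len(out) == 0

    def test_single_variant_sides_use_individual_p(self, make_assoc_table):
        disc = make_assoc_table([("v1", "G", 10, 90, 2, 98, 0.01, "case")])
        val = make_assoc_table([("w9", "G", 12, 120, 3, 163, 0.03, "case")])
        out = validate_genes(disc, val, pd.DataFrame(), pd.DataFrame(), 0.05)
        assert list(out["gene"]) == ["G"]
        assert out.loc[0, "p_disc"] == 0.01 and out.loc[0, "p_val"] == 0.03

    def test_multi_variant_gene_without_burden_is_pipeline_order_error(
        self, make_assoc_table
    ):
        disc = make_assoc_table(
            [(f"v{i}", "G", 20, 80, 2, 98, 0.001, "case") for i in range(2)]
        )
        val = make_assoc_table([("w1", "G", 12, 120, 3, 163, 0.03, "case")])
        with pytest.raises(PipelineOrderError):
            validate_genes(disc, val, pd.DataFrame(), pd.DataFrame(), 0.05)

    def test_directional_meta_p_above_alpha_blocks_validation(self, make_assoc_table):
        disc = make_assoc_table(
            [(f"v{i}", "G", 8, 92, 2, 98, 0.04, "case") for i in range(2)]
        )
        val = make_assoc_table([("w1", "G", 12, 120, 3, 163, 0.03, "case")])
        burden_d = pd.DataFrame([_burden_row("G", 0.12, 1.0)])
        out = validate_genes(disc, val, burden_d, pd.DataFrame(), 0.05)
        assert len(out) == 0

    def test_planted_rich_genes_recovered_from_simulation(self):
        """Truth recovery: planted hotspot genes validate; output coherent."""
        cfg = SimulationConfig(
            n_variants=1000, n_genes=100, n_planted_case=0, n_planted_ctrl=0,
            n_variant_rich_genes=3, variants_per_rich_gene=4,
            planted_or=4.0, planted_maf_ctrl=0.15, seed=37,
        )
        disc, val, truth = simulate_cohort_pair(cfg)
        gene_map = dict(zip(truth["variant_id"], truth["gene"]))
        res_d, _ = run_association(disc, gene_map=gene_map)
        res_v, _ = run_association(val, gene_map=gene_map)
        burden_d = run_burden(res_d)
        burden_v = run_burden(res_v)
        out = validate_genes(res_d, res_v, burden_d, burden_v, 0.05)
        rich = set(truth.loc[truth["status"] != "null", "gene"])
        assert len(rich) == 3
        recovered = rich & set(out["gene"])
        assert len(recovered) >= 2  # at least 2 of the 3 planted hotspots
        # every validated gene's direction matches its contributing variants
        for _, row in out.iterrows():
            for res in (res_d, res_v):
                sig = res[(res["gene"] == row["gene"]) & (res["p"] < 0.05)]
                assert set(sig["direction"]) == {row["direction"]}


class TestEnrichment:
    def test_degenerate_urn_all_successes(self):
        genes = {"A", "B", "C"}
        out = hypergeom_enrichment(genes, genes, {"S": genes})
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_zero_overlap_gives_p_one(self):
        universe = {f"G{i}" for i in range(1000)}
        validated = {f"G{i}" for i in range(20)}
        out = hypergeom_enrichment(
            validated, universe, {"S": {f"G{i}" for i in range(900, 950)}}
        )
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_matches_exact_tail_sum_oracle(self):
        universe = {f"G{i}" for i in range(1000)}
        validated = {f"G{i}" for i in range(33)}
        gene_set = {f"G{i}" for i in range(23, 73)}  # 50 genes, overlap 10
        out = hypergeom_enrichment(validated, universe, {"S": gene_set})
        assert out.loc[0, "overlap"] == 10
        assert out.loc[0, "p"] == pytest.approx(
            hypergeom_tail(10, 1000, 50, 33), rel=1e-10
        )

    def test_validated_gene_outside_universe_is_input_error(self):
        with pytest.raises(InputError, match="G99"):
            hypergeom_enrichment({"G99"}, {"G1"}, {"S": {"G1"}})

    def test_q_values_are_bh_adjusted_and_sorted(self):
        universe = {f"G{i}" for i in range(200)}
        validated = {f"G{i}" for i in range(15)}
        collections = {
            "hit": {f"G{i}" for i in range(12)},
            "miss": {f"G{i}" for i in range(100, 140)},
        }
        out = hypergeom_enrichment(validated, universe, collections)
        assert list(out["set"]) == ["hit", "miss"]
        assert (out["q"] >= out["p"] - 1e-15).all()
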