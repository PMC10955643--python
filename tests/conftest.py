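import numpy as np
import pandas as pd
import pytest

from xassoc.simulate import (
    Cohort,
    SimulationConfig,
    simulate_annotations,
    simulate_cohort_pair,
)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale paired-cohort design with all planted classes present."""
    return SimulationConfig(
        n_variants=800,
        n_genes=80,
        n_planted_case=4,
        n_planted_ctrl=4,
        n_variant_rich_genes=2,
        variants_per_rich_gene=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_pair(small_config):
    return simulate_cohort_pair(small_config)


@pytest.fixture(scope="session")
def small_annotations(small_pair, small_config):
    _, _, truth = small_pair
    panel = truth[["variant_id", "gene", "status"]].copy()
    panel[["chrom", "pos", "ref", "alt"]] = truth["variant_id"].str.split(
        ":", expand=True
    )
    panel["pos"] = panel["pos"].astype(int)
    rng = np.random.default_rng(small_config.seed + 1)
    return simulate_annotations(panel, small_config, rng)


@pytest.fixture
def tiny_cohort():
    """3 cases, 2 controls, 2 variants with hand-readable genotypes."""
    geno = np.array(
        [
            [2, 1],   # case: homalt, het
            [1, 0],   # case: het, homref
            [-1, 0],  # case: nocall, homref
            [0, 1],   # control: homref, het
            [0, -1],  # control: homref, nocall
        ],
        dtype=np.int8,
    )
    return Cohort(
        sample_ids=[f"S{i}" for i in range(5)],
        labels=np.array(["case", "case", "case", "control", "control"], dtype=object),
        genotypes=geno,
        variant_ids=["chr1:100:A:T", "chr1:200:G:C"],
    )


def assoc_row(variant_id, gene, case_alt, case_ref, ctrl_alt, ctrl_ref, p, direction):
    n_case = case_alt + case_ref
    n_ctrl = ctrl_alt + ctrl_ref
    return {
        "variant_id": variant_id,
        "gene": gene,
        "case_alt": case_alt,
        "case_ref": case_ref,
        "ctrl_alt": ctrl_alt,
        "ctrl_ref": ctrl_ref,
        "af_case": case_alt / n_case if n_case else np.nan,
        "af_ctrl": ctrl_alt / n_ctrl if n_ctrl else np.nan,
        "p": p,
        "direction": direction,
    }


@pytest.fixture
def make_assoc_table():
    """Factory for hand-built association tables."""

    def _make(rows):
        return pd.DataFrame([assoc_row(*r) for r in rows])

    return _make
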