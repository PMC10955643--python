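"""Cross-cohort validation and gene-set enrichment.

A variant validates when it is significant in both the discovery and the
validation cohort with the same enrichment direction; the combined evidence is
Berger's intersection-union test, whose p-value is the maximum of the two
per-cohort p-values (significant overall iff significant in each component).
Discordant-direction variants are excluded and reported separately.

A gene validates when each cohort contributes at least one significant variant
in the gene, all significant variants across both cohorts share one direction,
and each cohort's evidence passes on its own: for a cohort with two or more
significant variants in the gene, the matching directional subset meta-p must
be below alpha; for a cohort with exactly one, that variant's own allelic p
counts. Significant variants need not be the same physical variants in the
two cohorts.

Validated genes are finally screened for over-representation in user-supplied
gene-set collections with a one-sided hypergeometric test and BH adjustment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import InputError, PipelineOrderError
from .association import bh_adjust

VALIDATED_VARIANT_COLUMNS = [
    "variant_id", "gene", "af_case_disc", "af_ctrl_disc", "af_case_val",
    "af_ctrl_val", "p_disc", "p_val", "combined_p", "direction",
]
VALIDATED_GENE_COLUMNS = [
    "gene", "direction", "n_var_disc", "n_var_val", "p_disc", "p_val",
]


def iut_combine(p_disc: float, p_val: float) -> float:
    """Intersection-union combined p-value: max of the component p-values."""
    for p in (p_disc, p_val):
        if not (0.0 <= p <= 1.0):
            raise InputError(f"p-value outside [0, 1]: {p}")
    return max(p_disc, p_val)


def _check_shared_identity(disc: pd.DataFrame, val: pd.DataFrame) -> None:
    # variant_id is chrom:pos:ref:alt; a shared id with conflicting allele
    # frequencies is fine, but conflicting ref/alt encodings are not
    # representable (the alleles are part of the key), so only duplicated ids
    # within one table can collide.
    for name, df in (("discovery", disc), ("validation", val)):
        dup = df["variant_id"].duplicated()
        if dup.any():
            raise InputError(
                f"duplicate variant_id in {name} results: "
                f"{sorted(df.loc[dup, 'variant_id'])[:5]}"
            )


def validate_variants(
    disc: pd.DataFrame, val: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Variants significant in BOTH cohorts with identical direction.

    ``disc``/``val`` are association tables keyed by variant_id
    (chrom:pos:ref:alt). Returns ``(validated, discordant)``: ``validated``
    sorted by the intersection-union combined p-value, ``discordant`` listing
    variants significant in both cohorts whose directions disagree (discarded
    from further analyses).
    """
    _check_shared_identity(disc, val)
    merged = disc.merge(val, on="variant_id", suffixes=("_disc", "_val"))
    sig = merged[(merged["p_disc"] < alpha) & (merged["p_val"] < alpha)]
    directed = sig[
        (sig["direction_disc"] != "none") & (sig["direction_val"] != "none")
    ]
    coherent = directed["direction_disc"] == directed["direction_val"]

    validated = directed[coherent].copy()
    validated["direction"] = validated["direction_disc"]
    validated["gene"] = validated.get("gene_disc", "")
    validated["combined_p"] = np.maximum(validated["p_disc"], validated["p_val"])
    validated = (
        validated[VALIDATED_VARIANT_COLUMNS]
        .sort_values(["combined_p", "variant_id"], kind="mergesort")
        .reset_index(drop=True)
    )

    discordant = directed[~coherent].copy()
    discordant = discordant[
        ["variant_id", "p_disc", "p_val", "direction_disc", "direction_val"]
    ].reset_index(drop=True)
    return validated, discordant


def _gene_sig(assoc: pd.DataFrame, alpha: float) -> pd.DataFrame:
    sig = assoc[(assoc["p"] < alpha) & assoc["gene"].notna() & (assoc["gene"] != "")]
    return sig[sig["direction"] != "none"]


def _burden_lookup(burden: pd.DataFrame) -> dict[str, pd.Series]:
    if burden is None or len(burden) == 0:
        return {}
    return {row["gene"]: row for _, row in burden.iterrows()}


def validate_genes(
    disc_assoc: pd.DataFrame,
    val_assoc: pd.DataFrame,
    disc_burden: pd.DataFrame,
    val_burden: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Genes with coherent significant variants and per-cohort evidence < alpha.

    The two cohorts may contribute different physical variants; coherence is
    judged on significant variants only. Multi-variant cohort evidence is the
    directional subset meta-p (case-enriched genes use the case subset
    meta-p, control-enriched the control one); single-variant evidence is the
    variant's own allelic p. A multi-variant gene lacking a burden record is
    a pipeline-order error.
    """
    sig_d = _gene_sig(disc_assoc, alpha)
    sig_v = _gene_sig(val_assoc, alpha)
    burden_d = _burden_lookup(disc_burden)
    burden_v = _burden_lookup(val_burden)

    records = []
    for gene in sorted(set(sig_d["gene"]) & set(sig_v["gene"])):
        gd = sig_d[sig_d["gene"] == gene]
        gv = sig_v[sig_v["gene"] == gene]
        directions = set(gd["direction"]) | set(gv["direction"])
        if len(directions) != 1:
            continue  # incoherent: significant variants of mixed direction
        (direction,) = directions

        evidence = {}
        ok = True
        for label, grp, burden in (("disc", gd, burden_d), ("val", gv, burden_v)):
            if len(grp) >= 2:
                if gene not in burden:
                    raise PipelineOrderError(
                        f"gene {gene} has {len(grp)} significant variants in "
                        f"{label} but no burden record; run the burden stage first"
                    )
                row = burden[gene]
                if not row.get("processed", True):
                    ok = False
                    break
                p = row[
                    "subset_case_meta_p" if direction == "case"
                    else "subset_control_meta_p"
                ]
            else:
                p = float(grp["p"].iloc[0])
            if not (p < alpha):
                ok = False
                break
            evidence[label] = (len(grp), float(p))
        if not ok:
            continue
        records.append(
            {
                "gene": gene,
                "direction": direction,
                "n_var_disc": evidence["disc"][0],
                "n_var_val": evidence["val"][0],
                "p_disc": evidence["disc"][1],
                "p_val": evidence["val"][1],
            }
        )
    df = pd.DataFrame(records, columns=VALIDATED_GENE_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["direction", "n_var_disc", "p_disc"],
            ascending=[True, False, True], kind="mergesort",
        ).reset_index(drop=True)
    return df


def hypergeom_enrichment(
    validated_genes: set[str],
    universe: set[str],
    collections: dict[str, set[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of validated genes.

    For each collection set, the p-value is the upper tail
    P[X >= overlap] of Hypergeometric(|universe|, |set ∩ universe|,
    |validated|); q-values are BH-adjusted across collections. The universe
    should be the assayable gene space (e.g. all genes with >= 1 tested
    variant); validated genes must be inside it.
    """
    if not collections:
        raise InputError("no gene-set collections supplied")
    outside = validated_genes - universe
    if outside:
        raise InputError(
            f"validated genes outside the universe: {sorted(outside)[:5]}"
        )
    m_total = len(universe)
    n_drawn = len(validated_genes)
    records = []
    for name in sorted(collections):
        members = collections[name] & universe
        overlap = validated_genes & members
        k = len(overlap)
        # P[X >= k]; sf(k-1) is the exact upper tail
        p = float(hypergeom.sf(k - 1, m_total, len(members), n_drawn))
        records.append(
            {
                "set": name,
                "set_size": len(members),
                "overlap": k,
                "overlap_genes": ",".join(sorted(overlap)),
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(records)
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
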