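"""Gene-level burden analysis by exhaustive subset search.

For a gene carrying k significant variants, every non-empty subset of the k
variants is scored by pooling its allele counts (summing the case/control
alt and ref counts across the subset) and applying the exact allelic test to
the pooled 2x2 table. Three multiplicity-adjusted signals are reported:

* ``meta_p`` — the minimum subset p-value over all 2^k - 1 subsets,
  Bonferroni-multiplied by the number of subsets searched;
* ``subset_case_meta_p`` / ``subset_control_meta_p`` — the same search
  restricted to the gene's case-enriched (resp. control-enriched) variants,
  Bonferroni over its own 2^k_dir - 1 subsets; a direction with no eligible
  variants reports 1 and an empty best subset;
* ``subset_meta_p`` — Fisher's-method combination of the two directional
  meta-p-values: X = -2(ln p_case + ln p_ctrl) referred to chi-square with
  4 degrees of freedom.

This is a transparent surrogate for subset-based rare-variant burden testing
(exhaustive enumeration + pooled-count exact test + Bonferroni), exactly
checkable against a brute-force oracle; it is not a re-implementation of any
specific package's multiplicity adjustment. Variant direction within the gene
is taken from the marginal per-variant association result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import ConfigurationError, DesignError
from .association import AlleleTable, exact_allelic_test

BURDEN_COLUMNS = [
    "gene", "n_variants", "meta_p", "subset_case_meta_p",
    "subset_control_meta_p", "subset_meta_p",
    "best_case_subset", "best_control_subset", "processed",
]

DEFAULT_K_MAX = 12


@dataclass
class GeneBurdenResult:
    gene: str
    variant_ids: list[str]
    meta_p: float
    subset_case_meta_p: float
    subset_control_meta_p: float
    subset_meta_p: float
    best_case_subset: list[str] = field(default_factory=list)
    best_control_subset: list[str] = field(default_factory=list)


def eligible_genes(results: pd.DataFrame, alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """Genes with >= 2 variants significant at raw p < alpha.

    ``results`` is an association table carrying gene symbols. Returns a map
    gene -> its significant variants (with directions); genes with fewer than
    two significant variants are omitted.
    """
    sig = results[
        (results["p"] < alpha) & results["gene"].notna() & (results["gene"] != "")
    ]
    out: dict[str, pd.DataFrame] = {}
    for gene, grp in sig.groupby("gene", sort=True):
        if len(grp) >= 2:
            out[gene] = grp.sort_values("variant_id").reset_index(drop=True)
    return out


def _min_subset_p(rows: pd.DataFrame) -> tuple[float, tuple[str, ...], int]:
    """Exhaustive pooled-count search: (best raw p, best subset ids, n subsets).

    Ties on p go to the lexicographically smallest sorted variant-id tuple.
    Rows must be sorted by variant_id so combination order yields that
    tie-break directly.
    """
    k = len(rows)
    ids = list(rows["variant_id"])
    ca = rows["case_alt"].to_numpy(dtype=np.int64)
    cr = rows["case_ref"].to_numpy(dtype=np.int64)
    ta = rows["ctrl_alt"].to_numpy(dtype=np.int64)
    tr = rows["ctrl_ref"].to_numpy(dtype=np.int64)

    best_p, best_subset = np.inf, ()
    n_subsets = 0
    for size in range(1, k + 1):
        for idx in combinations(range(k), size):
            n_subsets += 1
            sel = list(idx)
            table = AlleleTable(
                int(ca[sel].sum()), int(cr[sel].sum()),
                int(ta[sel].sum()), int(tr[sel].sum()),
            )
            p, _ = exact_allelic_test(table)
            subset = tuple(ids[i] for i in idx)
            if p < best_p or (p == best_p and subset < best_subset):
                best_p, best_subset = p, subset
    return best_p, best_subset, n_subsets


def subset_burden(
    gene_variants: pd.DataFrame, k_max: int = DEFAULT_K_MAX
) -> GeneBurdenResult:
    """Exhaustive-subset burden result for one gene's significant variants.

    ``gene_variants`` carries one row per significant variant of a single gene
    with columns variant_id, gene, case_alt/case_ref/ctrl_alt/ctrl_ref and
    direction (from the marginal allelic test). Requires 2 <= k <= k_max;
    the 2^k enumeration cost is why k_max (default 12) is enforced —
    raise it explicitly to process larger genes.
    """
    k = len(gene_variants)
    if k < 2:
        raise DesignError("subset burden needs >= 2 significant variants")
    if k > k_max:
        raise ConfigurationError(
            f"gene has {k} significant variants, above k_max={k_max}; "
            f"raise k_max to enumerate 2^{k} - 1 subsets"
        )
    genes = set(gene_variants["gene"])
    if len(genes) != 1:
        raise DesignError(f"variants from multiple genes: {sorted(genes)}")
    (gene,) = genes
    rows = gene_variants.sort_values("variant_id").reset_index(drop=True)

    best_p, _, n_subsets = _min_subset_p(rows)
    meta_p = min(1.0, best_p * n_subsets)

    directional: dict[str, tuple[float, tuple[str, ...]]] = {}
    for direction in ("case", "control"):
        sub = rows[rows["direction"] == direction]
        if len(sub) == 0:
            directional[direction] = (1.0, ())
            continue
        p, subset, n = _min_subset_p(sub.reset_index(drop=True))
        directional[direction] = (min(1.0, p * n), subset)

    p_case, best_case = directional["case"]
    p_ctrl, best_ctrl = directional["control"]
    return GeneBurdenResult(
        gene=gene,
        variant_ids=list(rows["variant_id"]),
        meta_p=meta_p,
        subset_case_meta_p=p_case,
        subset_control_meta_p=p_ctrl,
        subset_meta_p=combine_subset_meta(p_case, p_ctrl),
        best_case_subset=list(best_case),
        best_control_subset=list(best_ctrl),
    )


def combine_subset_meta(p_case: float, p_ctrl: float) -> float:
    """Fisher's-method combination of the two directional meta-p-values.

    X = -2(ln p_case + ln p_ctrl) referred to a chi-square distribution with
    4 degrees of freedom; symmetric and decreasing in each argument. Zero
    inputs are clamped to the smallest positive float (with a warning).
    """
    ps = []
    for name, p in (("p_case", p_case), ("p_ctrl", p_ctrl)):
        if not (0.0 <= p <= 1.0):
            raise DesignError(f"{name} must be in [0, 1], got {p}")
        if p == 0.0:
            warnings.warn(
                f"{name}=0 clamped to the smallest positive float", RuntimeWarning
            )
            p = np.finfo(float).tiny
        ps.append(p)
    x = -2.0 * (np.log(ps[0]) + np.log(ps[1]))
    return float(chi2.sf(x, df=4))


def run_burden(
    assoc_results: pd.DataFrame, alpha: float = 0.05, k_max: int = DEFAULT_K_MAX
) -> pd.DataFrame:
    """Burden analysis over every eligible gene; one row per gene.

    Genes whose significant-variant count exceeds ``k_max`` are reported with
    ``processed=False`` and NaN p-values rather than silently truncated.
    """
    records = []
    for gene, grp in eligible_genes(assoc_results, alpha).items():
        if len(grp) > k_max:
            records.append(
                {
                    "gene": gene, "n_variants": len(grp), "meta_p": np.nan,
                    "subset_case_meta_p": np.nan, "subset_control_meta_p": np.nan,
                    "subset_meta_p": np.nan, "best_case_subset": "",
                    "best_control_subset": "", "processed": False,
                }
            )
            continue
        res = subset_burden(grp, k_max=k_max)
        records.append(
            {
                "gene": res.gene,
                "n_variants": len(res.variant_ids),
                "meta_p": res.meta_p,
                "subset_case_meta_p": res.subset_case_meta_p,
                "subset_control_meta_p": res.subset_control_meta_p,
                "subset_meta_p": res.subset_meta_p,
                "best_case_subset": ",".join(res.best_case_subset),
                "best_control_subset": ",".join(res.best_control_subset),
                "processed": True,
            }
        )
    df = pd.DataFrame(records, columns=BURDEN_COLUMNS)
    if len(df):
        df = df.sort_values(["subset_meta_p", "gene"], kind="mergesort").reset_index(
            drop=True
        )
    return df
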