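"""Per-variant exact allelic association testing.

The allelic test compares alternate-allele frequencies between cases and
controls. Each called genotype contributes two alleles (hom-ref -> 2 ref,
het -> 1+1, hom-alt -> 2 alt); no-calls contribute none. Conditional on the
margins of the resulting 2x2 allele-count table, the alt-allele count among
case alleles is hypergeometric under the null of equal frequencies; the
two-sided p-value sums the probabilities of all tables whose point probability
does not exceed that of the observed table (the point-probability rule, as in
Fisher's exact test).

The implementation works in exact integer arithmetic: table probabilities are
compared via their integer numerators C(n_case, k) * C(n_ctrl, m - k) over the
common denominator C(n, m), so ties are resolved exactly and the returned
p-value is the correctly rounded float of an exact rational.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, DesignError, InputError
from .simulate import Cohort, NOCALL

ASSOC_COLUMNS = [
    "variant_id", "gene", "case_alt", "case_ref", "ctrl_alt", "ctrl_ref",
    "af_case", "af_ctrl", "p", "direction",
]


@dataclass(frozen=True)
class AlleleTable:
    """2x2 allele-count table (alt/ref x case/control)."""

    case_alt: int
    case_ref: int
    ctrl_alt: int
    ctrl_ref: int

    def __post_init__(self):
        if min(self.case_alt, self.case_ref, self.ctrl_alt, self.ctrl_ref) < 0:
            raise InputError("allele counts must be non-negative")

    @property
    def n_case_alleles(self) -> int:
        return self.case_alt + self.case_ref

    @property
    def n_ctrl_alleles(self) -> int:
        return self.ctrl_alt + self.ctrl_ref

    @property
    def af_case(self) -> float:
        n = self.n_case_alleles
        return self.case_alt / n if n else float("nan")

    @property
    def af_ctrl(self) -> float:
        n = self.n_ctrl_alleles
        return self.ctrl_alt / n if n else float("nan")


def allele_counts(cohort: Cohort, variant_id: str) -> AlleleTable:
    """Tabulate case/control alt and ref allele counts for one variant."""
    col = cohort.variant_column(variant_id)
    case = cohort.case_mask
    return AlleleTable(*_counts_from_column(col, case))


def _counts_from_column(col: np.ndarray, case: np.ndarray) -> tuple[int, int, int, int]:
    called = col != NOCALL
    alt = np.where(called, col, 0)
    case_alt = int(alt[case].sum())
    ctrl_alt = int(alt[~case].sum())
    case_tot = 2 * int(called[case].sum())
    ctrl_tot = 2 * int(called[~case].sum())
    return case_alt, case_tot - case_alt, ctrl_alt, ctrl_tot - ctrl_alt


def _direction(af_case: float, af_ctrl: float) -> str:
    if np.isnan(af_case) or np.isnan(af_ctrl) or af_case == af_ctrl:
        return "none"
    return "case" if af_case > af_ctrl else "control"


def exact_allelic_test(table: AlleleTable) -> tuple[float, str]:
    """Two-sided exact test of equal case/control allele frequencies.

    Returns ``(p, direction)`` where direction is "case" when the alt allele
    is more frequent in cases, "control" when more frequent in controls and
    "none" at equality. Any zero table margin forces p = 1 (the conditional
    distribution is a point mass).
    """
    n_case = table.n_case_alleles
    n_ctrl = table.n_ctrl_alleles
    if n_case == 0 and n_ctrl == 0:
        raise DegenerateInputError("no called alleles in either group")
    m = table.case_alt + table.ctrl_alt  # alt-allele margin
    direction = _direction(table.af_case, table.af_ctrl)

    k_min = max(0, m - n_ctrl)
    k_max = min(n_case, m)
    numerators = [comb(n_case, k) * comb(n_ctrl, m - k) for k in range(k_min, k_max + 1)]
    n_obs = numerators[table.case_alt - k_min]
    included = sum(v for v in numerators if v <= n_obs)
    p = included / comb(n_case + n_ctrl, m)  # exact big-int division
    return min(p, 1.0), direction


def cohort_allele_counts(cohort: Cohort) -> pd.DataFrame:
    """Vectorised allele tabulation for every variant in the panel."""
    g = cohort.genotypes
    case = cohort.case_mask
    called = g != NOCALL
    alt = np.where(called, g, 0).astype(np.int64)
    case_alt = alt[case].sum(axis=0)
    ctrl_alt = alt[~case].sum(axis=0)
    case_tot = 2 * called[case].sum(axis=0)
    ctrl_tot = 2 * called[~case].sum(axis=0)
    return pd.DataFrame(
        {
            "variant_id": cohort.variant_ids,
            "case_alt": case_alt,
            "case_ref": case_tot - case_alt,
            "ctrl_alt": ctrl_alt,
            "ctrl_ref": ctrl_tot - ctrl_alt,
        }
    )


def run_association(
    cohort: Cohort,
    alpha: float = 0.05,
    gene_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exact allelic test for every variant; screen at raw p < alpha.

    Returns ``(all_results, significant)``, both sorted by ascending p with
    ties broken by variant_id. Screening is on raw p-values (the adjusted
    values from :func:`bh_adjust` are reported alongside, not used to screen).
    ``gene_map`` optionally attaches gene symbols per variant_id.
    """
    if not (0 < alpha <= 1):
        raise DesignError(f"alpha must be in (0, 1], got {alpha}")
    labels = set(cohort.labels)
    if labels != {"case", "control"}:
        raise DesignError(f"cohort must contain both classes, found {sorted(labels)}")

    counts = cohort_allele_counts(cohort)
    ps, dirs, af_case, af_ctrl, testable = [], [], [], [], []
    for row in counts.itertuples(index=False):
        table = AlleleTable(row.case_alt, row.case_ref, row.ctrl_alt, row.ctrl_ref)
        ok = table.n_case_alleles > 0 or table.n_ctrl_alleles > 0
        p, d = exact_allelic_test(table) if ok else (1.0, "none")
        ps.append(p)
        dirs.append(d)
        af_case.append(table.af_case)
        af_ctrl.append(table.af_ctrl)
        testable.append(ok)

    results = counts.assign(
        af_case=af_case, af_ctrl=af_ctrl, p=ps, direction=dirs, testable=testable,
        gene=[(gene_map or {}).get(v, "") for v in counts["variant_id"]],
    )
    results["p_bh"] = bh_adjust(results["p"].to_numpy())
    results = results.sort_values(["p", "variant_id"], kind="mergesort").reset_index(
        drop=True
    )
    # alpha = 1 is a vacuous screen: every testable variant passes
    mask = results["testable"] if alpha >= 1 else (results["p"] < alpha)
    significant = results[mask].reset_index(drop=True)
    return results, significant


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
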