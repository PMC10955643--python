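"""Site-level variant QC, functional prioritization and PCA structure check.

Site filters follow standard short-read joint-calling practice: a variant is
dropped when its depth-normalised quality score is low (DP < dp_min), or when
either strand-bias statistic is extreme (Fisher-test FS > fs_max, symmetric
odds ratio SOR > sor_max). Boundaries are retained (exclusion is strict
inequality). Functional prioritization keeps protein-altering coding classes
and canonical splice-flank variants, dropping everything else.

The PCA check guards against population substructure: genotypes are encoded
as alt-allele counts, no-calls mean-imputed per variant, and the leading
principal components' variance fractions inspected. A large PC1 fraction
flags a structured cohort; the flag is advisory (a logged warning), never a
hard stop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import ConfigurationError, DegenerateInputError
from .simulate import NOCALL, SELECTED_FUNC_CLASSES, Cohort

logger = logging.getLogger(__name__)

_QC_METRICS = ("DP", "FS", "SOR")


@dataclass
class QcThresholds:
    """Exclusion thresholds: drop DP < dp_min, FS > fs_max, SOR > sor_max."""

    dp_min: float = 20.0
    fs_max: float = 60.0
    sor_max: float = 40.0

    def __post_init__(self):
        for name in ("dp_min", "fs_max", "sor_max"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")


@dataclass
class StructureReport:
    variance_fractions: np.ndarray
    pc1_fraction: float
    structured: bool


def apply_site_filters(
    variants: pd.DataFrame,
    thresholds: QcThresholds | None = None,
    *,
    use_dp: bool = True,
    use_fs: bool = True,
    use_sor: bool = True,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Retain variants passing all enabled site filters, preserving order.

    ``variants`` is an annotation table with DP/FS/SOR columns. Returns the
    retained rows plus per-rule removal counts; a variant missing any enabled
    metric is removed and counted under ``missing_metric``. Each rule can be
    toggled off individually. Removal counts attribute each variant to every
    rule it fails.
    """
    thresholds = thresholds or QcThresholds()
    dp = pd.to_numeric(variants["DP"], errors="coerce")
    fs = pd.to_numeric(variants["FS"], errors="coerce")
    sor = pd.to_numeric(variants["SOR"], errors="coerce")

    missing = pd.Series(False, index=variants.index)
    if use_dp:
        missing |= dp.isna()
    if use_fs:
        missing |= fs.isna()
    if use_sor:
        missing |= sor.isna()

    fail_dp = use_dp & ~missing & (dp < thresholds.dp_min)
    fail_fs = use_fs & ~missing & (fs > thresholds.fs_max)
    fail_sor = use_sor & ~missing & (sor > thresholds.sor_max)
    removed = missing | fail_dp | fail_fs | fail_sor

    counts = {
        "dp": int(np.asarray(fail_dp).sum()),
        "fs": int(np.asarray(fail_fs).sum()),
        "sor": int(np.asarray(fail_sor).sum()),
        "missing_metric": int(missing.sum()),
    }
    return variants.loc[~removed].copy(), counts


def prioritize_functional(variants: pd.DataFrame) -> pd.DataFrame:
    """Keep protein-altering / canonical-splice variants; drop class "other".

    Retained classes: nonsynonymous SNVs, frameshift and non-frameshift
    insertions/deletions, stop gains/losses, canonical splice flanks.
    Order-preserving; an empty result is allowed.
    """
    keep = variants["func_class"].isin(SELECTED_FUNC_CLASSES)
    return variants.loc[keep].copy()


def dose_encode(genotypes: np.ndarray) -> np.ndarray:
    """Alt-allele counts {0,1,2} with per-variant mean imputation of no-calls."""
    x = genotypes.astype(float)
    x[genotypes == NOCALL] = np.nan
    col_means = np.nanmean(x, axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    nan_rows, nan_cols = np.where(np.isnan(x))
    x[nan_rows, nan_cols] = col_means[nan_cols]
    return x


def pca_structure_check(
    cohort: Cohort, n_components: int = 10, pc1_threshold: float = 0.05
) -> StructureReport:
    """Variance fractions of the top genotype principal components.

    ``structured`` is True when PC1 explains more than ``pc1_threshold`` of
    the total variance — advisory only, logged as a warning.
    """
    if cohort.n_samples < 2 or cohort.n_variants < 2:
        raise DegenerateInputError("PCA needs at least 2 samples and 2 variants")
    x = dose_encode(cohort.genotypes)
    x = x - x.mean(axis=0)
    if not np.any(x):
        raise DegenerateInputError("all-constant genotype matrix")
    k = min(n_components, cohort.n_samples - 1, cohort.n_variants)
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(x)
    fractions = pca.explained_variance_ratio_
    pc1 = float(fractions[0])
    structured = pc1 > pc1_threshold
    if structured:
        logger.warning(
            "PC1 explains %.1f%% of genotype variance (threshold %.1f%%): "
            "possible population substructure",
            100 * pc1, 100 * pc1_threshold,
        )
    return StructureReport(
        variance_fractions=fractions, pc1_fraction=pc1, structured=structured
    )
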