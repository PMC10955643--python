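"""Synthetic paired-cohort generator for extreme-phenotype association studies.

Emulates a two-stage design: a discovery cohort and an independent validation
cohort genotyped on the same variant panel. Most variants are null (one minor
allele frequency shared by cases and controls). A small set of planted variants
carries a genuine per-allele effect — case-enriched ("risk") or
control-enriched ("protective") — that is identical in both cohorts, so
cross-cohort validation has a ground truth to recover. A few "variant-rich"
genes carry several planted variants of a single direction, emulating
hotspot genes that gene-level burden testing should flag.

Genotypes are drawn per individual under Hardy-Weinberg equilibrium from the
group allele frequency; no-calls are applied independently per cell. Variants
are independent (no linkage disequilibrium) and, by default, there is no
population substructure; an optional two-subpopulation mode (allele-frequency
shift ``substructure_delta`` on half the panel) exists solely to exercise the
PCA structure check.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError

# genotype codes used throughout the package
NOCALL = -1
HOMREF = 0
HET = 1
HOMALT = 2

# functional classes retained by the prioritization step, plus "other"
SELECTED_FUNC_CLASSES = (
    "nonsynonymous_snv",
    "frameshift_ins",
    "frameshift_del",
    "nonframeshift_ins",
    "nonframeshift_del",
    "stopgain",
    "stoploss",
    "splice_canonical",
)

_BASES = np.array(list("ACGT"))


def risk_allele_frequency(af_ctrl: float, odds_ratio: float) -> float:
    """Case allele frequency giving a per-allele odds ratio over ``af_ctrl``.

    Solves OR = [af_case/(1-af_case)] / [af_ctrl/(1-af_ctrl)] for af_case:
    af_case = OR*af / (1 + af*(OR-1)).
    """
    return odds_ratio * af_ctrl / (1.0 + af_ctrl * (odds_ratio - 1.0))


@dataclass
class SimulationConfig:
    """Study-design parameters for :func:`simulate_cohort_pair`.

    Defaults mirror the emulated study: 50 cases / 50 controls in discovery,
    66 cases / 83 controls in validation, 16 individually planted coherent
    variants and 3 variant-rich genes with 4 same-direction variants each.
    """

    n_case_disc: int = 50
    n_ctrl_disc: int = 50
    n_case_val: int = 66
    n_ctrl_val: int = 83
    n_variants: int = 5000
    n_genes: int = 500
    maf_low: float = 0.01
    maf_high: float = 0.30
    n_planted_case: int = 8
    n_planted_ctrl: int = 8
    planted_or: float = 4.0
    planted_maf_ctrl: float = 0.15
    n_variant_rich_genes: int = 3
    variants_per_rich_gene: int = 4
    nocall_rate: float = 0.02
    seed: int = 0
    # fraction of NULL variants given failing site-QC metrics / non-selected
    # functional class, so downstream filtering stages have work to do
    qc_fail_rate: float = 0.02
    other_func_frac: float = 0.05
    # optional two-subpopulation mode: AF shift applied to half the variants
    # for the second half of the samples (0 = homogeneous population)
    substructure_delta: float = 0.0

    def validate(self) -> None:
        counts = {
            "n_case_disc": self.n_case_disc,
            "n_ctrl_disc": self.n_ctrl_disc,
            "n_case_val": self.n_case_val,
            "n_ctrl_val": self.n_ctrl_val,
            "n_variants": self.n_variants,
            "n_genes": self.n_genes,
            "n_planted_case": self.n_planted_case,
            "n_planted_ctrl": self.n_planted_ctrl,
            "n_variant_rich_genes": self.n_variant_rich_genes,
            "variants_per_rich_gene": self.variants_per_rich_gene,
        }
        for name, value in counts.items():
            if value < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {value}")
        if not (0.0 < self.maf_low <= self.maf_high < 0.5):
            raise ConfigurationError(
                f"need 0 < maf_low <= maf_high < 0.5, got "
                f"maf_low={self.maf_low}, maf_high={self.maf_high}"
            )
        if self.planted_or <= 1.0:
            raise ConfigurationError(f"planted_or must be > 1, got {self.planted_or}")
        if not (0.0 <= self.nocall_rate < 0.5):
            raise ConfigurationError(
                f"nocall_rate must be in [0, 0.5), got {self.nocall_rate}"
            )
        if not (0.0 < self.planted_maf_ctrl < 0.5):
            raise ConfigurationError(
                f"planted_maf_ctrl must be in (0, 0.5), got {self.planted_maf_ctrl}"
            )
        n_planted = (
            self.n_planted_case
            + self.n_planted_ctrl
            + self.n_variant_rich_genes * self.variants_per_rich_gene
        )
        if n_planted > self.n_variants:
            raise ConfigurationError(
                f"planted variants ({n_planted}) exceed n_variants "
                f"({self.n_variants})"
            )
        if self.n_genes < 1 or self.n_variants < 1:
            raise ConfigurationError("need at least 1 gene and 1 variant")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Cohort:
    """One case/control cohort over a fixed variant panel.

    ``genotypes`` is an ``(n_samples, n_variants)`` int8 matrix with codes
    -1 = no-call, 0 = hom-ref, 1 = het, 2 = hom-alt. ``labels`` holds
    "case"/"control" per sample. Ages and pack-years are carried as phenotype
    metadata only; no inference stage uses them.
    """

    sample_ids: list[str]
    labels: np.ndarray
    genotypes: np.ndarray
    variant_ids: list[str]
    age: np.ndarray = field(default=None)
    pack_years: np.ndarray = field(default=None)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n, m = self.genotypes.shape
        if n != len(self.sample_ids) or m != len(self.variant_ids):
            raise ConfigurationError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants"
            )
        if self.age is None:
            self.age = np.full(n, np.nan)
        if self.pack_years is None:
            self.pack_years = np.full(n, np.nan)
        self._variant_index = {v: j for j, v in enumerate(self.variant_ids)}

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def case_mask(self) -> np.ndarray:
        return self.labels == "case"

    def variant_column(self, variant_id: str) -> np.ndarray:
        from .errors import LookupError_

        try:
            j = self._variant_index[variant_id]
        except KeyError:
            raise LookupError_(f"unknown variant {variant_id!r}") from None
        return self.genotypes[:, j]

    def subset_variants(self, variant_ids: list[str]) -> "Cohort":
        """New cohort restricted (and re-ordered) to ``variant_ids``."""
        cols = [self._variant_index[v] for v in variant_ids]
        return Cohort(
            sample_ids=list(self.sample_ids),
            labels=self.labels.copy(),
            genotypes=self.genotypes[:, cols].copy(),
            variant_ids=list(variant_ids),
            age=self.age.copy(),
            pack_years=self.pack_years.copy(),
        )


def _assign_panel(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Lay out the variant panel: identities, gene assignment, truth status.

    Rich genes occupy the first gene slots and receive ``variants_per_rich_gene``
    planted variants each (directions alternate case/control per gene);
    individually planted variants land one-per-gene in the following slots;
    all remaining variants are null and are spread round-robin over the whole
    gene list.
    """
    genes = [f"GENE{g + 1:04d}" for g in range(cfg.n_genes)]
    rows = []
    vidx = 0

    def new_site():
        nonlocal vidx
        chrom = f"chr{(vidx % 22) + 1}"
        pos = 10_000 + 150 * vidx
        ref, alt = rng.choice(4, size=2, replace=False)
        vidx += 1
        return chrom, pos, _BASES[ref], _BASES[alt]

    # variant-rich genes: several same-direction planted variants per gene
    for g in range(cfg.n_variant_rich_genes):
        status = "planted_case" if g % 2 == 0 else "planted_ctrl"
        for _ in range(cfg.variants_per_rich_gene):
            chrom, pos, ref, alt = new_site()
            rows.append((chrom, pos, ref, alt, genes[g], status))
    # individually planted variants, one per (fresh) gene
    g0 = cfg.n_variant_rich_genes
    for i in range(cfg.n_planted_case + cfg.n_planted_ctrl):
        status = "planted_case" if i < cfg.n_planted_case else "planted_ctrl"
        gene = genes[(g0 + i) % cfg.n_genes]
        chrom, pos, ref, alt = new_site()
        rows.append((chrom, pos, ref, alt, gene, status))
    # null background: round-robin across the genes with no planted signal,
    # so planted hotspot/single-variant genes stay clean signal carriers
    n_planted_genes = g0 + cfg.n_planted_case + cfg.n_planted_ctrl
    null_genes = genes[n_planted_genes:] or genes
    n_null = cfg.n_variants - len(rows)
    for i in range(n_null):
        chrom, pos, ref, alt = new_site()
        rows.append((chrom, pos, ref, alt, null_genes[i % len(null_genes)], "null"))

    panel = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "gene", "status"]
    )
    panel["variant_id"] = (
        panel["chrom"]
        + ":"
        + panel["pos"].astype(str)
        + ":"
        + panel["ref"]
        + ":"
        + panel["alt"]
    )
    return panel


def _draw_genotypes(
    n_samples: int,
    af: np.ndarray,
    nocall_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """HWE genotypes: alt-allele count ~ Binomial(2, af) per sample/variant."""
    g = rng.binomial(2, af[None, :], size=(n_samples, af.size)).astype(np.int8)
    if nocall_rate > 0:
        miss = rng.random(g.shape) < nocall_rate
        g[miss] = NOCALL
    return g


def _make_cohort(
    prefix: str,
    n_case: int,
    n_ctrl: int,
    af_case: np.ndarray,
    af_ctrl: np.ndarray,
    panel: pd.DataFrame,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> Cohort:
    n = n_case + n_ctrl
    sample_ids = [f"{prefix}_CASE{i + 1:03d}" for i in range(n_case)] + [
        f"{prefix}_CTRL{i + 1:03d}" for i in range(n_ctrl)
    ]
    labels = np.array(["case"] * n_case + ["control"] * n_ctrl, dtype=object)

    if cfg.substructure_delta > 0:
        # two ancestry strata within each phenotype group: second half of each
        # group has AF shifted by delta on the first half of the panel
        half_panel = cfg.n_variants // 2
        geno = np.empty((n, cfg.n_variants), dtype=np.int8)
        for is_case, af in ((True, af_case), (False, af_ctrl)):
            idx = np.where(labels == ("case" if is_case else "control"))[0]
            split = len(idx) // 2
            af_shift = af.copy()
            af_shift[:half_panel] = np.clip(
                af_shift[:half_panel] + cfg.substructure_delta, 0.0, 0.99
            )
            geno[idx[:split]] = _draw_genotypes(split, af, cfg.nocall_rate, rng)
            geno[idx[split:]] = _draw_genotypes(
                len(idx) - split, af_shift, cfg.nocall_rate, rng
            )
    else:
        geno_case = _draw_genotypes(n_case, af_case, cfg.nocall_rate, rng)
        geno_ctrl = _draw_genotypes(n_ctrl, af_ctrl, cfg.nocall_rate, rng)
        geno = np.vstack([geno_case, geno_ctrl])

    age = np.concatenate(
        [rng.uniform(35, 56, n_case), rng.uniform(74, 87, n_ctrl)]
    ).round(1)
    pack = np.concatenate(
        [rng.uniform(15, 99, n_case), rng.uniform(30, 151, n_ctrl)]
    ).round(1)
    return Cohort(
        sample_ids=sample_ids,
        labels=labels,
        genotypes=geno,
        variant_ids=list(panel["variant_id"]),
        age=age,
        pack_years=pack,
    )


def simulate_annotations(
    panel: pd.DataFrame, cfg: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Site annotations with QC metrics and functional classes.

    Planted variants always pass QC and carry a selected functional class so
    ground-truth recovery is well-defined; a configured fraction of null
    variants fails one QC rule or is annotated "other" (e.g. synonymous).
    """
    m = len(panel)
    dp = rng.uniform(25, 120, m)
    fs = rng.uniform(0, 30, m)
    sor = rng.uniform(0, 3, m)
    func = rng.choice(SELECTED_FUNC_CLASSES, size=m)

    is_null = (panel["status"] == "null").to_numpy()
    null_idx = np.where(is_null)[0]
    n_fail = int(round(cfg.qc_fail_rate * null_idx.size))
    if n_fail:
        fail_idx = rng.choice(null_idx, size=n_fail, replace=False)
        rule = rng.integers(0, 3, size=n_fail)
        dp[fail_idx[rule == 0]] = rng.uniform(1, 19.5, (rule == 0).sum())
        fs[fail_idx[rule == 1]] = rng.uniform(60.5, 120, (rule == 1).sum())
        sor[fail_idx[rule == 2]] = rng.uniform(40.5, 80, (rule == 2).sum())
    n_other = int(round(cfg.other_func_frac * null_idx.size))
    if n_other:
        other_idx = rng.choice(null_idx, size=n_other, replace=False)
        func[other_idx] = "other"

    anno = panel[["variant_id", "chrom", "pos", "ref", "alt", "gene"]].copy()
    anno["func_class"] = func
    anno["var_type"] = np.where(
        pd.Series(func).str.contains("ins|del").to_numpy(), "indel", "snv"
    )
    anno["DP"] = dp.round(2)
    anno["FS"] = fs.round(3)
    anno["SOR"] = sor.round(3)
    return anno


def simulate_cohort_pair(
    config: SimulationConfig,
) -> tuple[Cohort, Cohort, pd.DataFrame]:
    """Generate a discovery/validation cohort pair plus a ground-truth table.

    Both cohorts share one variant panel and the same generating allele
    frequencies, so planted effects are coherent across cohorts by
    construction. Returns ``(discovery, validation, truth)`` where ``truth``
    has columns variant_id, status, gene, maf_ctrl, maf_case.

    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    panel = _assign_panel(config, rng)

    m = len(panel)
    maf_ctrl = rng.uniform(config.maf_low, config.maf_high, m)
    planted = panel["status"].to_numpy() != "null"
    maf_ctrl[planted] = config.planted_maf_ctrl

    maf_case = maf_ctrl.copy()
    is_case_enriched = (panel["status"] == "planted_case").to_numpy()
    is_ctrl_enriched = (panel["status"] == "planted_ctrl").to_numpy()
    maf_case[is_case_enriched] = risk_allele_frequency(
        maf_ctrl[is_case_enriched], config.planted_or
    )
    # protective: alt allele enriched in controls; apply the OR on the
    # control side symmetrically (same per-allele OR, opposite direction)
    maf_case[is_ctrl_enriched] = risk_allele_frequency(
        maf_ctrl[is_ctrl_enriched], 1.0 / config.planted_or
    )

    truth = panel[["variant_id", "status", "gene"]].copy()
    truth["maf_ctrl"] = maf_ctrl
    truth["maf_case"] = maf_case

    disc = _make_cohort(
        "DISC", config.n_case_disc, config.n_ctrl_disc, maf_case, maf_ctrl,
        panel, config, rng,
    )
    val = _make_cohort(
        "VAL", config.n_case_val, config.n_ctrl_val, maf_case, maf_ctrl,
        panel, config, rng,
    )
    return disc, val, truth
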