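# Methods

This note documents the statistical model behind each stage of `xassoc`, the
parameters that matter, the numerical choices, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Study design being modelled

The package implements a two-stage extreme-phenotype association design. Two
independent case-control cohorts are genotyped on a shared exome-wide variant
panel: a discovery cohort (default 50 extreme cases / 50 extreme controls)
and a larger validation cohort (default 66 / 83). Extreme cases are subjects
at the high-risk tail (here: heavy smokers, ≥ 15 pack-years, with disease by
age ≤ 56); extreme controls at the low-risk tail (heavy smokers, disease-free
at ≥ 72). Sampling the tails concentrates risk and protective alleles,
buying power at small n; the price is that single-cohort findings are noisy,
which is why every inference is gated on independent replication.

## Site QC and prioritization

Variants enter the analysis with three site-level metrics from a standard
joint-calling workflow: DP (depth-normalised variant quality), FS
(phred-scaled Fisher strand bias) and SOR (symmetric strand odds ratio). A
site is excluded when DP < 20, FS > 60 or SOR > 40; boundary values are
retained because the exclusion rules are written as strict inequalities.
Each rule is individually toggleable; a site missing any enabled metric is
removed and counted under `missing_metric`. Functional prioritization keeps
protein-altering coding classes — nonsynonymous SNVs, frameshift and
non-frameshift indels, stop gains/losses — and canonical splice-flank
variants; functional class is an annotation input, never recomputed from
coordinates.

The population-structure check encodes genotypes as alt-allele counts
{0, 1, 2} with per-variant mean imputation of no-calls, and examines the
variance fractions of the leading principal components. The cohort is
flagged "structured" when PC1 explains more than 5% of the variance — a
deliberately loose default, chosen because a PC1 near 1% is clearly
homogeneous while common ancestry splits push PC1 far above 5%. The flag is
advisory (a logged warning): this stage has no covariate machinery to adjust
with, so the right response to a structured cohort is a different analysis,
not a silent continuation.

## The exact allelic test

The association unit is the allele, not the genotype: each called genotype
contributes two alleles, no-calls contribute none (they are dropped, not
imputed). For a variant with case alt/ref counts (a, b) and control counts
(c, d), inference is conditional on the table margins; under
H₀: p_case = p_ctrl the case alt count follows the hypergeometric law

P(k) = C(n_case, k) C(n_ctrl, m − k) / C(n, m),  m = a + c, n = n_case + n_ctrl.

The two-sided p-value follows the point-probability rule: the sum of P(k′)
over all k′ in the support with P(k′) ≤ P(k_obs). The implementation
compares the integer numerators C(n_case, k)·C(n_ctrl, m−k) directly and
divides the summed numerator by C(n, m) once, so the comparison (including
exact ties, which occur at symmetric margins) is resolved in exact integer
arithmetic and the returned float is the correctly rounded value of an exact
rational. Any zero margin forces p = 1 (point-mass conditional
distribution); a table with no alleles in either group is a degenerate-input
error. Direction is "case" when the alt-allele frequency is higher in cases,
"control" when lower, "none" at exact equality.

This is the classical conditional (Fisher-style) exact test on allele
counts. The test is discrete and therefore conservative: at these allele
totals the realised type-I error at α = 0.05 is ~0.035–0.042 (measured on
20,000 null variants per cohort in the acceptance checks). Screening uses
raw p < 0.05 — deliberately not FDR-adjusted, since rare variants at n ≈ 100
samples rarely survive exome-wide adjustment; replication across cohorts is
the error control. BH-adjusted values are reported for context.

## Exhaustive-subset gene burden

Genes harbouring ≥ 2 significant variants are tested for an aggregate
signal. For k significant variants, every non-empty subset S is scored by
summing the four allele counts across S ("burden on the allele scale") and
applying the exact allelic test to the pooled table. Reported values:

* `meta_p` = min over all 2^k − 1 subsets of the pooled p, multiplied by
  2^k − 1 (Bonferroni over the search), capped at 1;
* `subset_case_meta_p` — the identical search restricted to the gene's
  case-enriched variants (direction taken from each variant's marginal
  test), Bonferroni over its own 2^k_case − 1 subsets; a direction with no
  eligible variants reports 1 and an empty best subset;
  `subset_control_meta_p` symmetrically;
* `subset_meta_p` — Fisher's-method combination of the two directional
  meta-p's, X = −2(ln p_case + ln p_ctrl) referred to χ² with 4 degrees of
  freedom (two p-values × 2 df each). A zero input is clamped to the
  smallest positive float with a warning.

Ties in the argmin go to the lexicographically smallest variant-id tuple, so
results are order-independent and reproducible. The 2^k cost is guarded by
`k_max` (default 12 → at most 4,095 subsets per gene); larger genes are
reported unprocessed rather than silently truncated. This design is a
transparent surrogate for subset-based rare-variant burden testing: it keeps
the structure — exhaustive subset search, directional case/control signals,
chi-square combination — while being exactly checkable against a brute-force
enumerate-and-retest oracle (the test suite verifies agreement to 1e-12).
It does not reproduce any specific package's multiplicity adjustment, and it
offers no weighted (Madsen–Browning) or variance-component (SKAT-type)
alternatives.

**A calibration caveat that users should understand.** Applied to variants
*not* selected for significance, the subset meta-p is conservative (measured
rejection ~0.01 at nominal 0.05 on pure-null genes). Applied as the pipeline
applies it — to variants that passed the p < 0.05 screen — it is strongly
anti-conservative, because the screened inputs carry selected noise; on a
pure-null simulation most eligible genes show subset_meta_p < 0.05. This is
inherent to screening-then-aggregating and is why a single cohort's burden
p-value is never treated as a finding: genes count only when the directional
evidence independently clears α in both cohorts.

## Cross-cohort validation

Variant identity across cohorts is `chrom:pos:ref:alt` (robust to annotation
drift; multi-allelic sites must be pre-split). A variant validates iff it is
significant in both cohorts with identical direction; combined evidence is
the intersection–union p, max(p_disc, p_val), which is exact for the
conjunction "significant in both". Significant-in-both variants with
opposite directions are excluded and reported separately.

A gene validates iff each cohort has ≥ 1 significant variant in it, all
significant variants in both cohorts share one direction (non-significant
variants of opposite direction are ignored), and per cohort: with ≥ 2
significant variants the matching directional subset meta-p is < α, with
exactly one the variant's own allelic p counts. The two cohorts may
contribute different physical variants — a gene is a replicated hotspot, not
necessarily a replicated site.

Under this conjunction rule false validations are quadratically rare: a null
variant must clear α in both cohorts with the same direction, so the
per-null false-validation probability is on the (α·P₀)² scale; measured
rates are ≲ 0.1% of nulls per run.

Validated genes are tested for over-representation in user-supplied GMT
collections with the one-sided hypergeometric tail
P[X ≥ overlap | N_universe, N_set, N_validated] and BH adjustment across
collections. The default universe is every gene carrying ≥ 1 tested variant
— the assayable space — rather than the whole genome.

## Classifiers

Features are allelic doses per validated variant: 0 no-call, 1 absent,
2 heterozygous, 3 homozygous alternate (the no-call code is deliberately
in-band: missingness is information for the classifier even though it is
excluded from the allele-count tests). A per-gene carried-variant count
encoding is available as an alternative input. Four families are tuned by
stratified K-fold (default K = 5, seeded shuffling) grid search on the
discovery cohort, selecting the hyperparameters with the highest mean
left-out-fold accuracy (ties → first point in deterministic grid order),
retraining the winner on the full discovery cohort and evaluating once on
the validation cohort. Dose codes are standardised for LR and SVC inside the
CV pipeline (fit on training folds only, so no leakage); tree models consume
raw codes. ROC-AUC uses predicted class-1 probabilities for LR/RF/GbRF and
the decision function for SVC. The default grids are modest, desk-scale
stand-ins (LR: C ∈ {0.01, 0.1, 1, 10}; SVC: kernel ∈ {linear, rbf} ×
C ∈ {0.1, 1, 10}; RF: depth ∈ {2, 4, ∞} at 200 trees; GbRF: 100/200 trees ×
learning rate {0.05, 0.1} × depth {2, 3}) and are fully configurable.

## The synthetic-data generator

The generator emulates the study conditions so that every downstream stage
is testable offline with a known answer:

* cohort sizes default to the study design (50/50 and 66/83);
* null variants draw one MAF ~ U(0.01, 0.30) shared by cases and controls
  (no allele-frequency spectrum is asserted beyond "common-to-low
  frequency");
* planted variants fix the control MAF at 0.15 and raise the case allele
  frequency to a per-allele odds ratio of 4 via
  af_case = OR·af / (1 + af·(OR − 1)), identically in both cohorts, so the
  planted signal is coherent by construction; protective variants apply
  OR⁻¹ symmetrically. The default effect size is a testing convenience —
  the true effect spectrum of validated extreme-phenotype variants is
  unknown — and 16 planted singles echoes the scale of a realistic validated
  set;
* hotspot genes (default 3) carry 4 same-direction planted variants each and
  contain no null variants, so gene-level recovery is well defined; null
  background is spread round-robin over the remaining genes;
* genotypes are Hardy–Weinberg draws from the group allele frequency;
  no-calls are i.i.d. per cell at rate 0.02 (typical post-QC exome
  missingness);
* site QC metrics and functional classes are generated so that ~2% of null
  variants fail one QC rule and ~5% are annotated "other"; planted variants
  always pass, keeping ground-truth recovery interpretable;
* ages and pack-years are drawn uniformly inside the extreme-phenotype
  bounds (cases 35–56 y, ≥ 15 pack-years; controls 74–87 y) and are carried
  as metadata only — no inference stage uses them;
* an optional two-subpopulation mode shifts allele frequencies by δ on half
  the panel for half of each phenotype group, solely to exercise the PCA
  check; by default the population is homogeneous, matching the design
  assumption the PCA check verifies.

What it does **not** emulate — and therefore what passing tests do not
certify about real data: linkage disequilibrium (variants are independent),
relatedness, genotyping batch effects, covariate confounding
(age/sex/ethnicity), site-specific missingness, and any realistic exome
allele-frequency spectrum or effect-size distribution. Recovery rates
measured here are upper bounds on what the same design would achieve on real
exomes.

## Numerical and reproducibility choices

* All p-value machinery is exact (integer/big-int arithmetic for the allelic
  test; scipy's χ²₄ survival function and hypergeometric tail otherwise).
* Result tables are sorted by (p, variant_id) so equal p-values have a
  reproducible order; subset ties break lexicographically.
* Every stochastic component (simulation, CV folds, tree models) is driven
  by one seed; the pipeline manifest records the config, seed, per-stage
  counts and a SHA-256 digest of every artifact, and a rerun with the same
  config is byte-identical.
* Degenerate inputs fail loudly: all-constant genotype matrices (PCA),
  empty allele tables, single-class cohorts, unstratifiable folds, feature
  mismatches between training and validation matrices.

## Problem sizes used in the shipped checks

The test suite and acceptance script run at the study's cohort sizes with
panels of 4,028–20,000 variants, 20 replicates for recovery statistics and
10 for classifier statistics — sizes chosen so the full exome-scale logic is
exercised while the whole battery completes in minutes on one CPU.

## Known limitations

* The allelic test assumes independent alleles (Hardy–Weinberg within
  groups); genotypic alternatives (dominance models, trend tests) are not
  provided.
* No covariate adjustment anywhere in the inference; the design argument
  (extreme sampling + replication) substitutes for modelling.
* The burden surrogate's Bonferroni-over-subsets is crude next to exact
  subset-multiplicity corrections; combined with screening it must be read
  as a ranking device, not a calibrated single-cohort test (see the caveat
  above).
* Gene-set enrichment treats genes as exchangeable; no size/length bias
  correction.
* The classifier stage reports honest held-out metrics but n ≈ 150
  validation samples give wide confidence bands; ROC curves are returned so
  users can inspect rather than trust a point estimate.
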