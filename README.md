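# xassoc

Two-cohort extreme-phenotype germline association analysis.

`xassoc` implements the statistical core of an extreme-phenotype case-control
design: compare the germline exomes of individuals at opposite tails of a risk
distribution — e.g. heavy smokers who developed lung adenocarcinoma unusually
young (*extreme cases*) versus heavy smokers still cancer-free at an advanced
age (*extreme controls*) — in a discovery cohort, then require every finding
to replicate coherently in an independent validation cohort. It is written for
statistical geneticists and bioinformaticians who want a transparent, exactly
testable implementation of each stage, plus a synthetic-cohort generator so
the whole pipeline can be exercised and calibrated without access to patient
genotypes.

## Methods at a glance

**Per-variant exact allelic test.** For each biallelic variant, called
genotypes contribute two alleles each, giving a 2×2 allele-count table
(alt/ref × case/control). Conditional on the margins, the case alt-allele
count *k* is hypergeometric under the null H₀: p_case = p_ctrl, and the
two-sided p-value is the point-probability rule

&nbsp;&nbsp;&nbsp;&nbsp;p = Σ { P(k′) : P(k′) ≤ P(k_obs) },

computed in exact integer arithmetic (correctly rounded to a float), so ties
are resolved exactly. Variants are screened at raw p < 0.05; BH-adjusted
values are reported alongside.

**Exhaustive-subset gene burden.** For a gene with k ≥ 2 significant
variants, every non-empty subset S of them is pooled (allele counts summed
over S) and retested; `meta_p` is the minimum subset p Bonferroni-multiplied
by 2^k − 1. The same search restricted to case-enriched (resp.
control-enriched) variants gives the directional `subset_case_meta_p` /
`subset_control_meta_p`, and the two are combined by Fisher's method,
X = −2(ln p_case + ln p_ctrl) ~ χ²₄, into `subset_meta_p`.

**Cross-cohort validation.** A variant validates when p < α in *both*
cohorts with the same enrichment direction; the combined evidence is Berger's
intersection–union test, p_comb = max(p_disc, p_val). A gene validates when
each cohort contributes ≥ 1 significant variant (the same or different
ones), all significant variants share one direction, and each cohort's
evidence — the directional subset meta-p where it has ≥ 2 significant
variants, the single variant's own p otherwise — is below α. Validated genes
are screened for gene-set over-representation with a one-sided
hypergeometric test and BH adjustment.

**Genotype classifiers.** Validated variants are encoded as allelic doses
(0 no-call, 1 absent, 2 heterozygous, 3 homozygous alternate); LR, SVC, RF
and GbRF are tuned by stratified K-fold cross-validated grid search on the
discovery cohort (selection metric: accuracy), retrained on all of discovery
and evaluated once on the validation cohort (accuracy, precision, recall,
F1, ROC-AUC; cases are the positive class).

**Synthetic cohorts.** Because real extreme-phenotype genotype data are not
publicly deposited, `xassoc.simulate` generates paired cohorts on one variant
panel: null variants with a shared MAF ~ U(0.01, 0.30), planted variants
whose case allele frequency is raised to a fixed per-allele odds ratio
(identically in both cohorts, so the signal is coherent), hotspot genes with
several same-direction planted variants, Hardy–Weinberg genotypes, and a
configurable no-call rate — together with a ground-truth table for recovery
scoring.

## Worked example

The numbered drivers under `analysis/` run the full study on the default
simulated design (50/50 discovery, 66/83 validation, 5,000 variants in 500
genes, 16 planted coherent variants plus 3 planted 4-variant hotspot genes):

```bash
python analysis/01_simulate.py
python analysis/02_qc.py
python analysis/03_association.py
python analysis/04_burden.py
python analysis/05_validate.py
python analysis/06_ml.py
```

which prints (abridged):

```
5000 variants in; removed by rule {'dp': 31, 'fs': 27, 'sor': 41, ...}; 4653 after functional prioritization
discovery: PC1 explains 1.4% of variance -> no substructure
disc: 168/4653 variants significant at p < 0.05; most significant chr17:12400:A:G in GENE0008 (p = 3.24e-07, enriched in cases)
val:  199/4653 variants significant at p < 0.05
disc: 19 genes with >= 2 significant variants; strongest GENE0001 (4 variants, subset meta-p = 2.65e-13)
24 validated variants (2 discordant discarded); planted recovery 22/28; false validations 2/4972 nulls
33 validated genes; hotspot genes recovered: ['GENE0001', 'GENE0002', 'GENE0003'] of ['GENE0001', 'GENE0002', 'GENE0003']
top enriched set: PLANTED_SIGNAL_SYNTHETIC (overlap 16/19, p = 1.79e-18, q = 1.79e-17)
model  cv_accuracy  cv_auc  val_accuracy  val_auc  precision  recall    f1
   LR         0.96   1.000         0.966    0.994      0.955   0.970 0.962
 GbRF         0.92   0.990         0.906    0.957      0.894   0.894 0.894
```

Reading: the QC stage removed 99 low-quality sites and 248 non-prioritized
(e.g. synonymous) variants; neither cohort shows population substructure;
the variant screen keeps ~3.5–4% of sites at p < 0.05 (the exact test is
slightly conservative at these sample sizes); cross-cohort coherence then
cuts thousands of candidates down to 24, of which 22 are truly planted; all
three planted hotspot genes validate at the gene level; the enrichment stage
pinpoints the synthetic "pathway" holding the planted genes; and the
dose-encoded classifiers separate the held-out validation cohort with
ROC-AUC ≈ 0.96–0.99 at this effect size.

The same pipeline is available as one command over a YAML config
(`xassoc run --config config.yaml`), or stage by stage
(`xassoc simulate|qc|assoc|burden|ml`).

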